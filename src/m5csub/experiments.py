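"""Comparison experiments: encoding schemes, window lengths, algorithms.

All comparisons over one dataset share its fixed train/test partition, so
differences between cells are attributable only to the varied factor.
Grids are fully deterministic under a seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import RegulatorDataset
from .encoders import SCHEME_NAMES, EncoderConfig, PCTable, get_encoder
from .models import crossvalidate, evaluate_independent
from .seq_io import TranscriptModel

#: lower-performing scheme pairs evaluated as combinations by default
DEFAULT_COMBINATIONS = ("eiip+autocov", "eiip+conposi")

WINDOW_LENGTHS = (21, 31, 41, 51, 61, 71, 81)


def _run_scheme(
    dataset: RegulatorDataset,
    scheme: str,
    algorithm: str,
    mode: str,
    pc: PCTable,
    config: EncoderConfig,
    seed: int,
) -> float:
    encoder = get_encoder(scheme, pc, config)
    if mode == "cv":
        windows, labels = dataset.train
        report = crossvalidate(windows, labels, algorithm, encoder, seed=seed)
    else:
        tr_w, tr_y = dataset.train
        te_w, te_y = dataset.test
        report = evaluate_independent(tr_w, tr_y, te_w, te_y, algorithm, encoder, seed=seed)
    return report.auroc


def compare_features(
    datasets: list[RegulatorDataset],
    schemes: tuple[str, ...] = SCHEME_NAMES,
    combinations: tuple[str, ...] = DEFAULT_COMBINATIONS,
    algorithm: str = "svm",
    mode: str = "independent",
    pc: PCTable | None = None,
    config: EncoderConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """AUROC per (scheme x task), one row per scheme plus combination rows
    and a row-average column.  Cells where a scheme cannot apply at the
    dataset's window length are NA."""
    pc = pc or PCTable.default()
    config = config or EncoderConfig()
    rows = {}
    for scheme in tuple(schemes) + tuple(combinations):
        cells = {}
        for ds in datasets:
            try:
                cells[ds.task] = _run_scheme(ds, scheme, algorithm, mode, pc, config, seed)
            except ValueError:
                cells[ds.task] = np.nan  # scheme inapplicable at this window length
        rows[scheme] = cells
    table = pd.DataFrame(rows).T
    table["average"] = table.mean(axis=1)
    table.index.name = "scheme"
    return table


def scan_window_lengths(
    dataset: RegulatorDataset,
    transcripts: dict[str, TranscriptModel],
    lengths: tuple[int, ...] = WINDOW_LENGTHS,
    scheme: str = "psnp",
    algorithm: str = "svm",
    pc: PCTable | None = None,
    config: EncoderConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Independent-test AUROC per window length; windows are re-extracted
    around the same centers (padded with N past transcript ends) and the
    encoder is refit at each length.  The best length is flagged."""
    pc = pc or PCTable.default()
    config = config or EncoderConfig()
    records = []
    for length in lengths:
        if length % 2 == 0 or length < 3:
            raise ValueError(f"window length must be odd and >= 3, got {length}")
        ds_l = dataset.with_flank((length - 1) // 2, transcripts)
        auc = _run_scheme(ds_l, scheme, algorithm, "independent", pc, config, seed)
        records.append({"length": length, "task": dataset.task, "auroc": auc})
    table = pd.DataFrame(records)
    table["best"] = table["auroc"] == table["auroc"].max()
    return table


def compare_algorithms(
    dataset: RegulatorDataset,
    algorithms: tuple[str, ...] = ("svm", "glm", "rf", "xgb"),
    scheme: str = "psnp",
    pc: PCTable | None = None,
    config: EncoderConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """AUROC/Acc/Sn/Sp per algorithm on the shared independent test split."""
    pc = pc or PCTable.default()
    config = config or EncoderConfig()
    tr_w, tr_y = dataset.train
    te_w, te_y = dataset.test
    rows = []
    for algorithm in algorithms:
        encoder = get_encoder(scheme, pc, config)
        rep = evaluate_independent(tr_w, tr_y, te_w, te_y, algorithm, encoder, seed=seed)
        rows.append(
            {
                "algorithm": algorithm,
                "task": dataset.task,
                "scheme": scheme,
                "auroc": rep.auroc,
                "acc": rep.acc,
                "sn": rep.sn,
                "sp": rep.sp,
            }
        )
    return pd.DataFrame(rows)
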