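"""Labeled dataset construction for regulator-substrate prediction.

A methylated cytosine is a positive for a regulator when its 41-nt window
overlaps at least one binding (CLIP) peak of that regulator on the same
strand.  Negatives are cytosines drawn 1:1 from the same transcripts.
Optional filters remove in-vitro-transcription artifacts and, under the
mature-mRNA model, non-exonic sites.  Near-duplicate windows are collapsed
by greedy representative clustering at 85% identity before the stratified
80/20 train/test split, so near-duplicates cannot leak across the split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .seq_io import (
    GenomicSite,
    LabeledWindow,
    PeakInterval,
    TranscriptModel,
    extract_window,
)

logger = logging.getLogger(__name__)

#: Overlap flank for site-to-peak mapping: a 41-nt window per site.
MAPPING_FLANK = 20


def label_substrates(
    m5c_sites: list[GenomicSite],
    clip_peaks: list[PeakInterval],
    flank: int = MAPPING_FLANK,
) -> list[GenomicSite]:
    """Sites whose (2*flank+1)-nt window intersects >= 1 same-strand peak."""
    if not clip_peaks:
        warnings.warn("empty peak set: no substrate can be labeled")
        return []
    trees: dict[tuple[str, str], IntervalTree] = {}
    for p in clip_peaks:
        trees.setdefault((p.chrom, p.strand), IntervalTree()).addi(p.start, p.end)
    positives = []
    for s in m5c_sites:
        tree = trees.get((s.chrom, s.strand))
        if tree is not None and tree.overlap(s.position - flank, s.position + flank + 1):
            positives.append(s)
    return positives


def filter_ivt(
    sites: list[GenomicSite], ivt_blacklist: list[GenomicSite]
) -> list[GenomicSite]:
    """Drop sites whose exact (chrom, position, strand) is blacklisted."""
    blocked = {b.key for b in ivt_blacklist}
    kept = [s for s in sites if s.key not in blocked]
    if sites and not kept:
        warnings.warn("every site was removed by the IVT blacklist")
    return kept


def assign_transcripts(
    sites: list[GenomicSite],
    transcripts: list[TranscriptModel],
    require_exonic: bool = False,
) -> dict[GenomicSite, TranscriptModel]:
    """Map each site to a transcript on its chromosome/strand whose span
    contains it; exonic hits are preferred.  Unassignable sites are dropped
    with a warning."""
    by_loc: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_loc.setdefault((t.chrom, t.strand), []).append(t)
    assigned: dict[GenomicSite, TranscriptModel] = {}
    dropped = 0
    for s in sites:
        best = None
        for t in by_loc.get((s.chrom, s.strand), []):
            if not t.contains(s.position):
                continue
            if t.in_exon(s.position):
                best = t
                break
            if best is None and not require_exonic:
                best = t
        if best is None:
            dropped += 1
        else:
            assigned[s] = best
    if dropped:
        warnings.warn(
            f"{dropped} site(s) could not be assigned to a transcript "
            "(outside every span, or outside exons where exonic placement is required)"
        )
    return assigned


def restrict_to_exons(
    sites: list[GenomicSite], transcripts: list[TranscriptModel]
) -> list[GenomicSite]:
    """Keep sites that fall inside an exon of some same-strand transcript
    (the mature-mRNA model); the full-transcript model bypasses this."""
    assigned = assign_transcripts(sites, transcripts, require_exonic=True)
    return [s for s in sites if s in assigned]


@dataclass(frozen=True)
class TranscriptSite:
    """A site resolved to transcript-oriented model coordinates."""

    transcript_id: str
    position: int
    label: int


def sample_negatives(
    positives: dict[str, list[int]],
    transcripts: dict[str, TranscriptModel],
    model_kind: str,
    rng: np.random.Generator,
) -> dict[str, list[int]]:
    """For each transcript with k positives, draw k cytosines uniformly
    without replacement from its remaining cytosines (spliced sequence under
    ``mature_mrna``, unspliced under ``full_transcript``).

    Returns {transcript_id: sorted negative positions}.  When a transcript
    runs out of eligible cytosines the deficit is recorded with a warning.
    """
    negatives: dict[str, list[int]] = {}
    deficit = 0
    for tid in sorted(positives):
        pos_set = set(positives[tid])
        seq = transcripts[tid].sequence(model_kind)
        eligible = [i for i, b in enumerate(seq) if b == "C" and i not in pos_set]
        k = min(len(pos_set), len(eligible))
        if k < len(pos_set):
            deficit += len(pos_set) - k
        chosen = sorted(rng.choice(len(eligible), size=k, replace=False)) if k else []
        negatives[tid] = [eligible[i] for i in chosen]
    if deficit:
        warnings.warn(f"negative sampling deficit: {deficit} fewer negatives than positives")
    return negatives


def sequence_identity(a: str, b: str) -> float:
    """Fraction of matching positions between equal-length windows.
    'N' never matches, including against another 'N'."""
    if len(a) != len(b):
        raise ValueError("identity is defined for equal-length windows")
    return sum(x == y and x != "N" for x, y in zip(a, b)) / len(a)


def remove_redundant(
    windows: list[LabeledWindow], identity_threshold: float = 0.85
) -> list[LabeledWindow]:
    """Greedy representative clustering: in input order, a window joins the
    first cluster whose representative shares >= threshold identity,
    otherwise founds a new cluster.  Representatives are returned, so every
    retained pair has identity < threshold."""
    if not windows:
        return []
    length = len(windows[0].sequence)
    # byte matrix enables vectorized identity against all representatives
    reps: list[LabeledWindow] = []
    rep_mat = np.empty((0, length), dtype="S1")
    for w in windows:
        if len(w.sequence) != length:
            raise ValueError("all windows must share one length")
        arr = np.frombuffer(w.sequence.encode(), dtype="S1")
        if len(reps):
            matches = (rep_mat == arr) & (arr != b"N")
            if (matches.sum(axis=1) / length >= identity_threshold).any():
                continue
        reps.append(w)
        rep_mat = np.vstack([rep_mat, arr[None, :]])
    return reps


@dataclass
class RegulatorDataset:
    """A labeled, split dataset for one regulator and transcript model."""

    regulator: str
    model_kind: str
    positives: list[LabeledWindow]
    negatives: list[LabeledWindow]
    train_idx: list[int] = field(default_factory=list)
    test_idx: list[int] = field(default_factory=list)
    seed: int = 0
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def windows(self) -> list[LabeledWindow]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows])

    def _subset(self, idx: list[int]) -> tuple[list[str], np.ndarray]:
        all_w = self.windows
        return [all_w[i].sequence for i in idx], np.array([all_w[i].label for i in idx])

    @property
    def train(self) -> tuple[list[str], np.ndarray]:
        return self._subset(self.train_idx)

    @property
    def test(self) -> tuple[list[str], np.ndarray]:
        return self._subset(self.test_idx)

    @property
    def task(self) -> str:
        return f"{self.regulator}:{self.model_kind}"

    def manifest(self) -> pd.DataFrame:
        rows = []
        split = {i: "train" for i in self.train_idx}
        split.update({i: "test" for i in self.test_idx})
        for i, w in enumerate(self.windows):
            rows.append(
                {
                    "id": w.window_id,
                    "transcript": w.transcript_id,
                    "position": w.position,
                    "label": w.label,
                    "split": split.get(i, "unsplit"),
                    "regulator": self.regulator,
                    "model_kind": self.model_kind,
                }
            )
        return pd.DataFrame(rows)

    def with_flank(self, flank: int, transcripts: dict[str, TranscriptModel]) -> "RegulatorDataset":
        """Re-extract every window at a new flank around the same centers,
        keeping the split.  Used by the window-length scan."""
        def rebuild(ws: list[LabeledWindow]) -> list[LabeledWindow]:
            out = []
            for w in ws:
                seq = transcripts[w.transcript_id].sequence(self.model_kind)
                out.append(
                    LabeledWindow(
                        sequence=extract_window(seq, w.position, flank),
                        label=w.label,
                        transcript_id=w.transcript_id,
                        regulator=w.regulator,
                        window_id=w.window_id,
                        position=w.position,
                    )
                )
            return out

        return RegulatorDataset(
            regulator=self.regulator,
            model_kind=self.model_kind,
            positives=rebuild(self.positives),
            negatives=rebuild(self.negatives),
            train_idx=list(self.train_idx),
            test_idx=list(self.test_idx),
            seed=self.seed,
            stage_counts=dict(self.stage_counts),
        )


def split_train_test(
    dataset: RegulatorDataset, train_frac: float = 0.8, seed: int = 0
) -> RegulatorDataset:
    """Stratified split: floor(train_frac * n) training members per class,
    deterministic under the seed.  Requires >= 5 members per class so the
    training part still supports 5-fold cross-validation."""
    n_pos, n_neg = len(dataset.positives), len(dataset.negatives)
    if min(n_pos, n_neg) < 5:
        raise ValueError(
            f"need >= 5 windows per class to split, got {n_pos} positives / {n_neg} negatives"
        )
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for offset, n in ((0, n_pos), (n_pos, n_neg)):
        order = rng.permutation(n) + offset
        n_train = int(np.floor(train_frac * n))
        train_idx.extend(int(i) for i in order[:n_train])
        test_idx.extend(int(i) for i in order[n_train:])
    dataset.train_idx = sorted(train_idx)
    dataset.test_idx = sorted(test_idx)
    dataset.seed = seed
    return dataset


def build_dataset(
    m5c_sites: list[GenomicSite],
    clip_peaks: list[PeakInterval],
    transcripts: list[TranscriptModel],
    regulator: str,
    model_kind: str = "mature_mrna",
    flank: int = MAPPING_FLANK,
    ivt_blacklist: list[GenomicSite] | None = None,
    identity_threshold: float = 0.85,
    train_frac: float = 0.8,
    seed: int = 0,
) -> RegulatorDataset:
    """Run the full labeling pipeline and return a split dataset.

    Stages (counts of surviving sites are logged and recorded):
    peak overlap -> IVT filter -> exon filter (mature model) -> transcript
    assignment -> 1:1 negative sampling -> window extraction -> per-class
    redundancy removal -> class re-balancing -> stratified 80/20 split.
    """
    counts = {"sites_in": len(m5c_sites)}
    positives_g = label_substrates(m5c_sites, clip_peaks, flank=MAPPING_FLANK)
    counts["post_peak_overlap"] = len(positives_g)
    if ivt_blacklist:
        positives_g = filter_ivt(positives_g, ivt_blacklist)
    counts["post_ivt"] = len(positives_g)
    if model_kind == "mature_mrna":
        positives_g = restrict_to_exons(positives_g, transcripts)
    counts["post_exon"] = len(positives_g)

    tx_by_id = {t.transcript_id: t for t in transcripts}
    assigned = assign_transcripts(
        positives_g, transcripts, require_exonic=(model_kind == "mature_mrna")
    )
    pos_by_tx: dict[str, list[int]] = {}
    for site, tx in assigned.items():
        mpos = tx.genomic_to_model(site.position, model_kind)
        if mpos is None:
            continue
        pos_by_tx.setdefault(tx.transcript_id, []).append(mpos)
    for tid in pos_by_tx:
        pos_by_tx[tid] = sorted(set(pos_by_tx[tid]))
    counts["positives"] = sum(len(v) for v in pos_by_tx.values())

    rng = np.random.default_rng(seed)
    neg_by_tx = sample_negatives(pos_by_tx, tx_by_id, model_kind, rng)
    counts["negatives"] = sum(len(v) for v in neg_by_tx.values())

    def to_windows(by_tx: dict[str, list[int]], label: int) -> list[LabeledWindow]:
        out = []
        for tid in sorted(by_tx):
            seq = tx_by_id[tid].sequence(model_kind)
            for p in by_tx[tid]:
                out.append(
                    LabeledWindow(
                        sequence=extract_window(seq, p, flank),
                        label=label,
                        transcript_id=tid,
                        regulator=regulator,
                        window_id=f"{tid}:{p}:{label}",
                        position=p,
                    )
                )
        return out

    pos_windows = remove_redundant(to_windows(pos_by_tx, 1), identity_threshold)
    neg_windows = remove_redundant(to_windows(neg_by_tx, 0), identity_threshold)
    counts["post_redundancy_pos"] = len(pos_windows)
    counts["post_redundancy_neg"] = len(neg_windows)

    # redundancy removal can unbalance the classes; trim the larger at random
    n = min(len(pos_windows), len(neg_windows))
    if len(pos_windows) > n:
        keep = sorted(rng.choice(len(pos_windows), size=n, replace=False))
        pos_windows = [pos_windows[i] for i in keep]
    if len(neg_windows) > n:
        keep = sorted(rng.choice(len(neg_windows), size=n, replace=False))
        neg_windows = [neg_windows[i] for i in keep]
    counts["balanced_per_class"] = n

    ds = RegulatorDataset(
        regulator=regulator,
        model_kind=model_kind,
        positives=pos_windows,
        negatives=neg_windows,
        stage_counts=counts,
    )
    split_train_test(ds, train_frac=train_frac, seed=seed)
    for stage, value in counts.items():
        logger.info("%s %s: %s = %d", regulator, model_kind, stage, value)
    return ds
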