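"""Sequence-derived feature encodings for C-centered RNA windows.

Eight schemes are provided behind a uniform fit/transform contract:

========== ============================================== ==========
scheme     description                                    dimension
========== ============================================== ==========
conposi    dinucleotide composition                       16
onehot     per-position binary encoding                   4L
psnp       position-specific dinucleotide propensity      L - 1
eiip       electron-ion interaction pseudopotential       L
autocov    lagged auto-covariance of physicochemical      10 * Lam
           dinucleotide property profiles
crosscov   lagged cross-covariance between property pairs 90 * Lam
pseknc     type-1 pseudo k-tuple nucleotide composition   4^k + lam
chemprop   ring / functional-group / hydrogen-bond code   3L
========== ============================================== ==========

with L the window length and Lam = min(lag, L - 2).  Only ``psnp`` has a
non-trivial ``fit``: its propensity matrix is a class-contrast statistic
and must be estimated on training windows only (it is re-fit inside each
cross-validation fold by the evaluation layer).

Window sequences are RNA strings over {A, C, G, U, N}; 'N' marks positions
padded past a transcript end.  Each encoder defines its N handling: zero
blocks for positional codes, exclusion from frequency denominators, and
mean-imputed (zero-deviation) property values for the covariance family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import product
from typing import IO, Iterable, Sequence

import numpy as np

BASES = "ACGU"
DINUCLEOTIDES = tuple(a + b for a, b in product(BASES, repeat=2))
_DI_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

#: Electron-ion interaction pseudopotential per nucleotide.
EIIP_VALUES = {"A": 0.1260, "U": 0.1335, "C": 0.1340, "G": 0.0806, "N": 0.0}

#: Chemical-property code: (amino/keto, ring count, hydrogen bonds).
CHEMPROP_VALUES = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "U": (0, 0, 1),
    "N": (0, 0, 0),
}

_ONEHOT = {
    "A": (1, 0, 0, 0),
    "C": (0, 1, 0, 0),
    "G": (0, 0, 1, 0),
    "U": (0, 0, 0, 1),
    "N": (0, 0, 0, 0),
}


@dataclass
class EncoderConfig:
    """Tunable encoder parameters.

    ``lag`` is the maximum covariance lag; it is adapted per window to
    min(lag, L - 2) so short windows in a length scan stay encodable.
    PseKNC parameters follow the common type-1 defaults.
    """

    lag: int = 39
    pseknc_k: int = 3
    pseknc_lambda: int = 5
    pseknc_w: float = 0.05

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if not 0 < self.pseknc_w < 1:
            raise ValueError("pseknc weight must be in (0, 1)")


class PCTable:
    """Physicochemical property values per dinucleotide (n_properties x 16).

    When ``normalize`` is set (the default for the bundled table) each
    property row is standardized to mean 0 / sd 1 across the 16
    dinucleotides, the convention of the covariance and PseKNC encoders.
    """

    def __init__(self, names: Sequence[str], matrix: np.ndarray, normalize: bool = True):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(names), 16):
            raise ValueError(f"PC matrix must be (n_properties, 16), got {matrix.shape}")
        self.names = list(names)
        self.normalized = normalize
        if normalize:
            mean = matrix.mean(axis=1, keepdims=True)
            sd = matrix.std(axis=1, keepdims=True)
            if np.any(sd == 0):
                raise ValueError("constant property row cannot be standardized")
            matrix = (matrix - mean) / sd
        self.matrix = matrix

    @property
    def n_properties(self) -> int:
        return len(self.names)

    @classmethod
    def from_tsv(cls, stream: str | IO, normalize: bool = True) -> "PCTable":
        """Load a property table from TSV: header row of 16 dinucleotides,
        one property per row."""
        own = not hasattr(stream, "read")
        handle = open(stream) if own else stream
        try:
            header = handle.readline().rstrip("\n").split("\t")
            cols = [c.replace("T", "U") for c in header[1:]]
            if sorted(cols) != sorted(DINUCLEOTIDES):
                raise ValueError("PC table header must list the 16 dinucleotides")
            order = [cols.index(d) for d in DINUCLEOTIDES]
            names, rows = [], []
            for line in handle:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                names.append(fields[0])
                vals = [float(x) for x in fields[1:]]
                rows.append([vals[i] for i in order])
        finally:
            if own:
                handle.close()
        return cls(names, np.array(rows), normalize=normalize)

    @classmethod
    def default(cls) -> "PCTable":
        """The bundled 10-property RNA dinucleotide table (standardized)."""
        ref = resources.files("m5csub") / "data" / "rna_dinucleotide_properties.tsv"
        with ref.open() as handle:
            return cls.from_tsv(handle)


def _window_dinucleotides(window: str) -> list[str]:
    return [window[j : j + 2] for j in range(len(window) - 1)]


def encode_conposi(window: str) -> np.ndarray:
    """Dinucleotide composition: 16 frequencies in the fixed order AA..UU,
    normalized by the number of N-free dinucleotides."""
    if len(window) < 2:
        raise ValueError("conposi needs a window of length >= 2")
    counts = np.zeros(16)
    for di in _window_dinucleotides(window):
        idx = _DI_INDEX.get(di)
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        warnings.warn("window has no N-free dinucleotides; conposi is all zero")
        return counts
    return counts / total


def encode_onehot(window: str) -> np.ndarray:
    """Per-position binary code, A=(1,0,0,0) ... U=(0,0,0,1), N all-zero."""
    return np.array([v for base in window for v in _ONEHOT[base]], dtype=float)


def encode_eiip(window: str) -> np.ndarray:
    """Electron-ion interaction pseudopotential profile."""
    return np.array([EIIP_VALUES[base] for base in window])


def encode_chemprop(window: str) -> np.ndarray:
    """Chemical-property triplets (amino/keto, rings, hydrogen bonds)."""
    return np.array([v for base in window for v in CHEMPROP_VALUES[base]], dtype=float)


@dataclass
class PSNPModel:
    """Position-specific dinucleotide propensity matrix.

    ``Z[i, j] = F+(diN_i | j) - F-(diN_i | j)``: the difference between the
    frequencies of dinucleotide i at window position j in the positive and
    negative training sets.  Entries lie in [-1, 1]; each column sums to
    zero when the training windows carry no N at that position.
    """

    Z: np.ndarray
    window_length: int

    def __post_init__(self) -> None:
        if self.Z.shape != (16, self.window_length - 1):
            raise ValueError("Z must be 16 x (L-1)")


def _position_frequencies(windows: Sequence[str], length: int) -> np.ndarray:
    counts = np.zeros((16, length - 1))
    for w in windows:
        for j, di in enumerate(_window_dinucleotides(w)):
            idx = _DI_INDEX.get(di)
            if idx is not None:
                counts[idx, j] += 1
    totals = counts.sum(axis=0)
    freqs = np.zeros_like(counts)
    nonzero = totals > 0
    freqs[:, nonzero] = counts[:, nonzero] / totals[nonzero]
    return freqs


def fit_psnp(pos_windows: Sequence[str], neg_windows: Sequence[str]) -> PSNPModel:
    """Estimate the propensity matrix from labeled training windows."""
    if not pos_windows or not neg_windows:
        raise ValueError("both classes must be non-empty to fit a propensity matrix")
    length = len(pos_windows[0])
    if length < 2:
        raise ValueError("windows must have length >= 2")
    for w in list(pos_windows) + list(neg_windows):
        if len(w) != length:
            raise ValueError("all windows must share one length")
    z = _position_frequencies(pos_windows, length) - _position_frequencies(
        neg_windows, length
    )
    return PSNPModel(Z=z, window_length=length)


def encode_psnp(window: str, model: PSNPModel) -> np.ndarray:
    """Score each of the L-1 dinucleotides by its positional propensity;
    dinucleotides containing N score 0."""
    if len(window) != model.window_length:
        raise ValueError(
            f"window length {len(window)} != model length {model.window_length}"
        )
    out = np.zeros(model.window_length - 1)
    for j, di in enumerate(_window_dinucleotides(window)):
        idx = _DI_INDEX.get(di)
        if idx is not None:
            out[j] = model.Z[idx, j]
    return out


def _property_deviations(window: str, pc: PCTable) -> np.ndarray:
    """Per-window property profile deviations, shape (n_properties, L-1).

    Each dinucleotide maps to its property column; a dinucleotide containing
    N takes the window mean of that property (zero deviation).  Deviations
    are from the mean over all L-1 dinucleotides of the window.
    """
    dis = _window_dinucleotides(window)
    idxs = np.array([_DI_INDEX.get(d, -1) for d in dis])
    valid = idxs >= 0
    profile = np.zeros((pc.n_properties, len(dis)))
    if valid.any():
        profile[:, valid] = pc.matrix[:, idxs[valid]]
        mean = profile[:, valid].mean(axis=1, keepdims=True)
    else:
        mean = np.zeros((pc.n_properties, 1))
    profile[:, ~valid] = np.broadcast_to(mean, (pc.n_properties, (~valid).sum()))
    return profile - mean


def _effective_lag(window_length: int, lag: int) -> int:
    lam = min(lag, window_length - 2)
    if lam < 1:
        raise ValueError(f"window of length {window_length} too short for lagged covariance")
    return lam


def encode_autocov(window: str, pc: PCTable | None = None, lag: int = 39) -> np.ndarray:
    """Auto-covariance of each property profile at lags 1..min(lag, L-2).

    AC_lam(i) = (1/(L-1-lam)) * sum_j dev_i[j] * dev_i[j+lam].
    Output is property-major: (AC_1(p1)..AC_Lam(p1), AC_1(p2), ...).
    """
    pc = pc or PCTable.default()
    lam_max = _effective_lag(len(window), lag)
    dev = _property_deviations(window, pc)
    n_pos = dev.shape[1]
    out = np.empty((pc.n_properties, lam_max))
    for lam in range(1, lam_max + 1):
        out[:, lam - 1] = (dev[:, : n_pos - lam] * dev[:, lam:]).sum(axis=1) / (
            n_pos - lam
        )
    return out.ravel()


def encode_crosscov(window: str, pc: PCTable | None = None, lag: int = 39) -> np.ndarray:
    """Cross-covariance between ordered property pairs (i1 != i2) at lags
    1..min(lag, L-2); each property is centered by its own window mean."""
    pc = pc or PCTable.default()
    if pc.n_properties < 2:
        raise ValueError("cross-covariance needs at least 2 properties")
    lam_max = _effective_lag(len(window), lag)
    dev = _property_deviations(window, pc)
    n_pos = dev.shape[1]
    blocks = []
    for i1 in range(pc.n_properties):
        for i2 in range(pc.n_properties):
            if i1 == i2:
                continue
            vals = [
                (dev[i1, : n_pos - lam] * dev[i2, lam:]).sum() / (n_pos - lam)
                for lam in range(1, lam_max + 1)
            ]
            blocks.append(vals)
    return np.array(blocks).ravel()


def encode_pseknc(
    window: str,
    pc: PCTable | None = None,
    k: int = 3,
    lam: int = 5,
    w: float = 0.05,
) -> np.ndarray:
    """Type-1 pseudo k-tuple nucleotide composition (4^k + lam dimensions).

    The first 4^k components are down-weighted k-tuple frequencies; the
    remaining ``lam`` are sequence-order correlation factors built from the
    mean squared difference of standardized dinucleotide property vectors:

        theta_j = (1/(L-1-j)) * sum_m Theta(m, m+j),
        Theta(m, n) = mean_i (H_i(m) - H_i(n))^2,
        d_u = f_u / (1 + w * sum theta)   for u <= 4^k,
        d_u = w * theta_j / (1 + w * sum theta)   otherwise.
    """
    pc = pc or PCTable.default()
    L = len(window)
    if L < k + lam + 1:
        raise ValueError(f"window of length {L} too short for k={k}, lambda={lam}")
    kmers = ["".join(t) for t in product(BASES, repeat=k)]
    kmer_index = {m: i for i, m in enumerate(kmers)}
    counts = np.zeros(len(kmers))
    for j in range(L - k + 1):
        idx = kmer_index.get(window[j : j + k])
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        warnings.warn("window has no N-free k-tuples; frequencies are all zero")
        freqs = counts
    else:
        freqs = counts / total

    # standardized property profile; N dinucleotides sit at the table mean (0)
    dis = _window_dinucleotides(window)
    idxs = np.array([_DI_INDEX.get(d, -1) for d in dis])
    H = np.zeros((pc.n_properties, len(dis)))
    valid = idxs >= 0
    H[:, valid] = pc.matrix[:, idxs[valid]]

    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diffs = H[:, :-j] - H[:, j:]
        thetas[j - 1] = np.mean(diffs**2, axis=0).mean() if diffs.size else 0.0
    denom = freqs.sum() + w * thetas.sum()
    if denom == 0:
        return np.zeros(len(kmers) + lam)
    return np.concatenate([freqs, w * thetas]) / denom


def combine_features(*vectors: np.ndarray) -> np.ndarray:
    """Concatenate feature vectors from the same window."""
    return np.concatenate([np.asarray(v, dtype=float) for v in vectors])


# ---------------------------------------------------------------------------
# fit/transform wrappers


class Encoder:
    """Uniform interface over the encoding schemes.

    ``fit(pos_windows, neg_windows)`` is a no-op for every scheme except the
    positional propensity encoder, whose matrix is a training-set statistic.
    """

    name: str = "base"
    trainable: bool = False

    def fit(self, pos_windows: Sequence[str], neg_windows: Sequence[str]) -> "Encoder":
        return self

    def encode(self, window: str) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def transform(self, windows: Iterable[str]) -> np.ndarray:
        return np.array([self.encode(w) for w in windows])

    def dim(self, window_length: int) -> int:
        raise NotImplementedError

    def clone(self) -> "Encoder":
        """A fresh, unfitted copy (used to re-fit inside CV folds)."""
        return self


class ConposiEncoder(Encoder):
    name = "conposi"

    def encode(self, window: str) -> np.ndarray:
        return encode_conposi(window)

    def dim(self, window_length: int) -> int:
        return 16


class OneHotEncoder(Encoder):
    name = "onehot"

    def encode(self, window: str) -> np.ndarray:
        return encode_onehot(window)

    def dim(self, window_length: int) -> int:
        return 4 * window_length


class EiipEncoder(Encoder):
    name = "eiip"

    def encode(self, window: str) -> np.ndarray:
        return encode_eiip(window)

    def dim(self, window_length: int) -> int:
        return window_length


class ChemPropEncoder(Encoder):
    name = "chemprop"

    def encode(self, window: str) -> np.ndarray:
        return encode_chemprop(window)

    def dim(self, window_length: int) -> int:
        return 3 * window_length


class PsnpEncoder(Encoder):
    name = "psnp"
    trainable = True

    def __init__(self) -> None:
        self.model: PSNPModel | None = None

    def fit(self, pos_windows: Sequence[str], neg_windows: Sequence[str]) -> "PsnpEncoder":
        self.model = fit_psnp(pos_windows, neg_windows)
        return self

    def encode(self, window: str) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("propensity encoder must be fit before encoding")
        return encode_psnp(window, self.model)

    def dim(self, window_length: int) -> int:
        return window_length - 1

    def clone(self) -> "PsnpEncoder":
        return PsnpEncoder()


class AutoCovEncoder(Encoder):
    name = "autocov"

    def __init__(self, pc: PCTable | None = None, lag: int = 39) -> None:
        self.pc = pc or PCTable.default()
        self.lag = lag

    def encode(self, window: str) -> np.ndarray:
        return encode_autocov(window, self.pc, self.lag)

    def dim(self, window_length: int) -> int:
        return self.pc.n_properties * _effective_lag(window_length, self.lag)


class CrossCovEncoder(Encoder):
    name = "crosscov"

    def __init__(self, pc: PCTable | None = None, lag: int = 39) -> None:
        self.pc = pc or PCTable.default()
        self.lag = lag

    def encode(self, window: str) -> np.ndarray:
        return encode_crosscov(window, self.pc, self.lag)

    def dim(self, window_length: int) -> int:
        p = self.pc.n_properties
        return p * (p - 1) * _effective_lag(window_length, self.lag)


class PseKNCEncoder(Encoder):
    name = "pseknc"

    def __init__(self, pc: PCTable | None = None, k: int = 3, lam: int = 5, w: float = 0.05):
        self.pc = pc or PCTable.default()
        self.k, self.lam, self.w = k, lam, w

    def encode(self, window: str) -> np.ndarray:
        return encode_pseknc(window, self.pc, self.k, self.lam, self.w)

    def dim(self, window_length: int) -> int:
        return 4**self.k + self.lam


class CombinedEncoder(Encoder):
    """Concatenation of several schemes applied to the same window."""

    def __init__(self, parts: Sequence[Encoder]) -> None:
        self.parts = list(parts)
        self.name = "+".join(p.name for p in parts)

    @property
    def trainable(self) -> bool:  # type: ignore[override]
        return any(p.trainable for p in self.parts)

    def fit(self, pos_windows, neg_windows) -> "CombinedEncoder":
        for p in self.parts:
            p.fit(pos_windows, neg_windows)
        return self

    def encode(self, window: str) -> np.ndarray:
        return combine_features(*(p.encode(window) for p in self.parts))

    def dim(self, window_length: int) -> int:
        return sum(p.dim(window_length) for p in self.parts)

    def clone(self) -> "CombinedEncoder":
        return CombinedEncoder([p.clone() for p in self.parts])


SCHEME_NAMES = (
    "conposi",
    "onehot",
    "psnp",
    "eiip",
    "autocov",
    "crosscov",
    "pseknc",
    "chemprop",
)


def get_encoder(
    scheme: str,
    pc: PCTable | None = None,
    config: EncoderConfig | None = None,
) -> Encoder:
    """Build an encoder by scheme name; '+'-joined names concatenate schemes
    (e.g. ``"eiip+autocov"``)."""
    config = config or EncoderConfig()
    if "+" in scheme:
        return CombinedEncoder([get_encoder(s, pc, config) for s in scheme.split("+")])
    scheme = scheme.lower()
    if scheme == "conposi":
        return ConposiEncoder()
    if scheme in ("onehot", "one_hot"):
        return OneHotEncoder()
    if scheme == "psnp":
        return PsnpEncoder()
    if scheme == "eiip":
        return EiipEncoder()
    if scheme in ("autocov", "autocor"):
        return AutoCovEncoder(pc, config.lag)
    if scheme in ("crosscov", "crosscor"):
        return CrossCovEncoder(pc, config.lag)
    if scheme == "pseknc":
        return PseKNCEncoder(pc, config.pseknc_k, config.pseknc_lambda, config.pseknc_w)
    if scheme in ("chemprop", "chemproper"):
        return ChemPropEncoder()
    raise ValueError(f"unknown encoding scheme {scheme!r}")
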