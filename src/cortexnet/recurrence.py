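"""Symbolic recurrence quantification of activation-order sequences.

Complex network activity can be screened for repeating firing motifs by
treating the temporally ordered sequence of activated cell IDs as a
symbolic time series.  The sequence is embedded into overlapping
subsequences of length ``m``; the distance between two subsequences is
the number of non-identical corresponding members (a Hamming distance),
so two fully identical subsequences have a mutual distance of zero.
Thresholding the pairwise distances yields a binary recurrence matrix.
Deterministic dynamics shows up as diagonal lines of slope 1: if
subsequence *i* resembles subsequence *j*, then *i*+1 tends to resemble
*j*+1.  Total recurrence is the sum of the (off-diagonal) recurrence
matrix, and determinism is the same sum restricted to entries lying in
diagonal runs of length two or greater.  Significance is assessed by
recomputing the statistic on uniformly shuffled surrogate sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivationSequence",
    "EmbeddingConfig",
    "RecurrenceResult",
    "SurrogateResult",
    "embed",
    "subseq_distance",
    "recurrence_matrix",
    "quantify",
    "surrogate_test",
    "distance_matrix",
    "plot_distance_matrix",
]

STATISTICS = ("recurrence_total", "determinism_raw", "det_fraction")


@dataclass
class ActivationSequence:
    """An ordered list of activated cell IDs (symbols over a finite alphabet)."""

    symbols: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols)
        if self.symbols.ndim != 1 or self.symbols.size < 1:
            raise ValueError("symbols must be a non-empty 1-D sequence")

    def __len__(self) -> int:
        return int(self.symbols.size)

    @property
    def alphabet(self) -> np.ndarray:
        return np.unique(self.symbols)

    def codes(self) -> np.ndarray:
        """Symbols recoded as integers 0..A-1 (order of ``np.unique``)."""
        _, inv = np.unique(self.symbols, return_inverse=True)
        return inv.astype(np.int64)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Recurrence-analysis parameters.

    ``m`` is the embedding dimension (subsequence length, customarily
    between 3 and 10).  ``distance_threshold`` is the integer mismatch
    threshold: entry (i, j) of the recurrence matrix is 1 when the
    distance is strictly less than it, so the default of 1 demands exact
    subsequence identity.  ``theiler_window`` excludes the band
    |i - j| <= w from all quantification sums (0 excludes only the line
    of identity).  ``l_min`` is the minimum diagonal run length counted
    as deterministic.
    """

    m: int = 5
    distance_threshold: int = 1
    theiler_window: int = 0
    l_min: int = 2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not 1 <= self.distance_threshold <= self.m:
            raise ValueError("distance_threshold must lie in [1, m]")
        if self.theiler_window < 0:
            raise ValueError("theiler_window must be >= 0")
        if self.l_min < 2:
            raise ValueError("l_min must be >= 2")


@dataclass
class RecurrenceResult:
    """Recurrence matrix plus its quantification.

    ``recurrence_total`` sums the recurrence matrix outside the Theiler
    band; ``determinism_raw`` restricts that sum to entries within
    slope-1 diagonal runs of length >= ``l_min``; ``det_fraction`` is
    their ratio (0 when there is no recurrence at all).
    """

    R: np.ndarray
    config: EmbeddingConfig
    recurrence_total: int = 0
    determinism_raw: int = 0

    @property
    def det_fraction(self) -> float:
        if self.recurrence_total == 0:
            return 0.0
        return self.determinism_raw / self.recurrence_total

    def statistic(self, name: str) -> float:
        if name not in STATISTICS:
            raise ValueError(f"unknown statistic {name!r}; expected one of {STATISTICS}")
        return float(getattr(self, name))


@dataclass
class SurrogateResult:
    """Outcome of a shuffle-based significance test.

    ``p_value`` uses the add-one permutation estimator
    ``(1 + #{surrogate >= observed}) / (1 + n_surrogates)``, whose
    smallest achievable value is ``1 / (n_surrogates + 1)``.
    """

    statistic_name: str
    observed: float
    surrogate_values: np.ndarray
    n_surrogates: int
    p_value: float
    seed: int
    config: EmbeddingConfig


def embed(seq: ActivationSequence | np.ndarray, m: int) -> np.ndarray:
    """All overlapping subsequences of length ``m``, as an (L - m + 1, m) matrix."""
    symbols = seq.symbols if isinstance(seq, ActivationSequence) else np.asarray(seq)
    L = symbols.size
    if m < 1:
        raise ValueError("embedding dimension m must be >= 1")
    if m > L:
        raise ValueError(f"embedding dimension m={m} exceeds sequence length {L}")
    return np.lib.stride_tricks.sliding_window_view(symbols, m).copy()


def subseq_distance(a, b) -> int:
    """Number of non-identical corresponding members of two subsequences."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"subsequence lengths differ: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def _mismatch_counts(embedded: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances between embedded rows (N x N int matrix)."""
    n, m = embedded.shape
    out = np.zeros((n, n), dtype=np.int32)
    for col in range(m):
        c = embedded[:, col]
        out += (c[:, None] != c[None, :]).astype(np.int32)
    return out


def _row_codes(embedded: np.ndarray) -> np.ndarray:
    """Collapse each embedded row to a single integer; equal codes <=> equal rows."""
    _, elem = np.unique(embedded.ravel(), return_inverse=True)
    elem = elem.reshape(embedded.shape).astype(np.int64)
    n_sym = int(elem.max()) + 1 if elem.size else 1
    m = embedded.shape[1]
    if m * np.log(max(n_sym, 2)) < 62 * np.log(2):
        powers = n_sym ** np.arange(m - 1, -1, -1, dtype=np.int64)
        return elem @ powers
    _, codes = np.unique(elem, axis=0, return_inverse=True)
    return codes.astype(np.int64)


def recurrence_matrix(
    embedded: np.ndarray, config: EmbeddingConfig | None = None
) -> np.ndarray:
    """Binary recurrence matrix: R[i, j] = 1 iff distance(i, j) < threshold.

    The full matrix is returned (symmetric, unit main diagonal); the
    Theiler-window exclusion applies only when quantifying.
    """
    config = config or EmbeddingConfig()
    embedded = np.asarray(embedded)
    if embedded.ndim != 2:
        raise ValueError("embedded must be a 2-D subsequence matrix")
    if config.distance_threshold == 1:
        codes = _row_codes(embedded)
        R = codes[:, None] == codes[None, :]
    else:
        R = _mismatch_counts(embedded) < config.distance_threshold
    return R.astype(np.int8)


def _zero_theiler(R: np.ndarray, w: int) -> np.ndarray:
    Rq = R.astype(np.int8).copy()
    n = Rq.shape[0]
    for k in range(-min(w, n - 1), min(w, n - 1) + 1):
        np.fill_diagonal(Rq[max(0, -k) :, max(0, k) :], 0)
    return Rq


def _determinism_sum(Rq: np.ndarray, l_min: int) -> int:
    if l_min == 2:
        up = np.zeros_like(Rq)
        up[1:, 1:] = Rq[:-1, :-1]
        down = np.zeros_like(Rq)
        down[:-1, :-1] = Rq[1:, 1:]
        return int((Rq & (up | down)).sum())
    n = Rq.shape[0]
    total = 0
    for off in range(-(n - 1), n):
        d = np.diagonal(Rq, offset=off)
        padded = np.concatenate([[0], d, [0]])
        edges = np.diff(padded)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        lengths = ends - starts
        total += int(lengths[lengths >= l_min].sum())
    return total


def quantify(R: np.ndarray, config: EmbeddingConfig | None = None) -> RecurrenceResult:
    """Recurrence and determinism sums of a binary recurrence matrix.

    Entries with |i - j| <= ``theiler_window`` are excluded from both
    sums.  Because the exclusion band is a union of whole diagonals, it
    cannot split a diagonal run elsewhere in the matrix.
    """
    config = config or EmbeddingConfig()
    R = np.asarray(R)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be a square matrix")
    Rq = _zero_theiler(R, config.theiler_window)
    rec = int(Rq.sum())
    det = _determinism_sum(Rq, config.l_min)
    return RecurrenceResult(
        R=R, config=config, recurrence_total=rec, determinism_raw=det
    )


def _statistic_for_codes(codes: np.ndarray, config: EmbeddingConfig, name: str) -> float:
    emb = embed(codes, config.m)
    R = recurrence_matrix(emb, config)
    return quantify(R, config).statistic(name)


def surrogate_test(
    seq: ActivationSequence | np.ndarray,
    config: EmbeddingConfig | None = None,
    statistic_name: str = "determinism_raw",
    n_surrogates: int = 1999,
    seed: int = 0,
) -> SurrogateResult:
    """Shuffle-based significance test of a recurrence statistic.

    Surrogates are uniformly random permutations of the symbol sequence
    (symbol counts preserved); the statistic is recomputed for each with
    the identical embedding configuration, and the p-value is the add-one
    permutation estimator.  Results are reproducible for a fixed seed.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if statistic_name not in STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic_name!r}; expected one of {STATISTICS}"
        )
    config = config or EmbeddingConfig()
    if not isinstance(seq, ActivationSequence):
        seq = ActivationSequence(symbols=np.asarray(seq))
    codes = seq.codes()
    observed = _statistic_for_codes(codes, config, statistic_name)
    rng = np.random.default_rng(seed)
    surr = np.empty(n_surrogates)
    for i in range(n_surrogates):
        surr[i] = _statistic_for_codes(rng.permutation(codes), config, statistic_name)
    p = (1 + int(np.count_nonzero(surr >= observed))) / (1 + n_surrogates)
    return SurrogateResult(
        statistic_name=statistic_name,
        observed=observed,
        surrogate_values=surr,
        n_surrogates=n_surrogates,
        p_value=p,
        seed=seed,
        config=config,
    )


def distance_matrix(seq: ActivationSequence | np.ndarray, m: int = 5) -> np.ndarray:
    """Pairwise mismatch distances between all embedded subsequences."""
    emb = embed(seq, m)
    return _mismatch_counts(emb)


def plot_distance_matrix(
    seq: ActivationSequence | np.ndarray,
    m: int = 5,
    path: str | None = None,
    cmap: str = "RdBu",
):
    """Heat-map rendering of the subsequence distance matrix.

    Low distances (recurrent firing sequences) appear at the blue end of
    the default colour map.  Returns the matplotlib figure; saves to
    ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    D = distance_matrix(seq, m)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(D, origin="lower", cmap=cmap, interpolation="nearest")
    ax.set_xlabel("subsequence index")
    ax.set_ylabel("subsequence index")
    fig.colorbar(im, ax=ax, label=f"mismatch distance (m={m})")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
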