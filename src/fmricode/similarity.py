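"""Representational similarity analysis and functional smoothness.

An encoder f is functionally smooth when similar inputs map to similar
representations, ``sim(x1, x2) ∝ sim(f(x1), f(x2))``.  With Pearson
correlation as both the similarity measure and the measure of
proportionality, the smoothness statistic is the correlation between the
input-pair and output-pair similarity lists over a set of stimulus pairs
(self-pairs excluded as degenerate).  The module also provides pairwise
similarity matrices for RSA and the Gini coefficient of activation
sparseness, and accepts externally produced activation matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import DegenerateInputError

__all__ = [
    "SimilarityMatrix",
    "SmoothnessResult",
    "pearson_similarity",
    "representational_similarity_matrix",
    "functional_smoothness",
    "smoothness_from_similarities",
    "gini_sparseness",
    "prototype_distortion_pairs",
]


def pearson_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation between two vectors.

    Constant inputs raise :class:`DegenerateInputError` rather than
    silently returning 0: a saturated representation carries no
    similarity information and must be handled explicitly by the caller.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 2")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(da @ da)
    nb = np.sqrt(db @ db)
    if na == 0.0 or nb == 0.0:
        raise DegenerateInputError("Pearson similarity undefined for a constant vector")
    if np.array_equal(da, db):  # self-similarity is exactly 1, no rounding
        return 1.0
    return float(np.clip((da @ db) / (na * nb), -1.0, 1.0))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise Pearson similarities over a set of representations.

    ``values`` is symmetric with unit diagonal; entries involving a
    constant (zero-variance) representation are NaN, with the offending
    representations listed in ``degenerate``.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    degenerate: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=tuple(str(c) for c in df.columns), values=df.to_numpy(dtype=float))


def representational_similarity_matrix(
    reps: np.ndarray | list[np.ndarray], labels: list[str] | None = None
) -> SimilarityMatrix:
    """All pairwise Pearson similarities of a stimuli-by-units matrix.

    Accepts any array-like of representations, including activation
    matrices exported from external models (rows = stimuli).
    """
    mat = np.asarray(reps, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least 2 representations of common length")
    n = mat.shape[0]
    if labels is None:
        labels = [f"s{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count does not match representation count")
    sds = mat.std(axis=1)
    degenerate = tuple(labels[i] for i in np.flatnonzero(sds == 0.0))
    values = np.full((n, n), np.nan)
    ok = sds > 0.0
    if ok.any():
        sub = np.corrcoef(mat[ok])
        values[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(values, np.where(ok, 1.0, np.nan))
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return SimilarityMatrix(labels=tuple(labels), values=values, degenerate=degenerate)


@dataclass(frozen=True)
class SmoothnessResult:
    """The functional-smoothness statistic and its constituent pair similarities."""

    statistic: float
    input_sims: np.ndarray = field(repr=False)
    output_sims: np.ndarray = field(repr=False)
    aggregation: str = "pooled"
    n_excluded_pairs: int = 0

    @property
    def n_pairs(self) -> int:
        return self.input_sims.size

    def to_json(self, path=None) -> str:
        payload = {
            "statistic": self.statistic,
            "aggregation": self.aggregation,
            "n_pairs": self.n_pairs,
            "n_excluded_pairs": self.n_excluded_pairs,
            "input_sims": self.input_sims.tolist(),
            "output_sims": self.output_sims.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def prototype_distortion_pairs(stimulus_set) -> list[tuple[np.ndarray, np.ndarray]]:
    """The default pair set: (prototype, distortion level i) for every level."""
    p = stimulus_set.prototype.values
    return [(p, d) for d in stimulus_set.distortions]


def smoothness_from_similarities(
    input_sims: np.ndarray, output_sims: np.ndarray, *, n_excluded: int = 0
) -> SmoothnessResult:
    """Smoothness statistic from precomputed similarity lists.

    The statistic is the Pearson correlation of the two lists; at least
    3 pairs with variance on both sides are required.
    """
    input_sims = np.asarray(input_sims, dtype=float)
    output_sims = np.asarray(output_sims, dtype=float)
    if input_sims.shape != output_sims.shape:
        raise ValueError("similarity lists must have equal length")
    if input_sims.size < 3:
        raise DegenerateInputError("need at least 3 pairs for the smoothness statistic")
    stat = pearson_similarity(input_sims, output_sims)
    return SmoothnessResult(
        statistic=stat, input_sims=input_sims, output_sims=output_sims, n_excluded_pairs=n_excluded
    )


def functional_smoothness(stimulus_pairs, encoder) -> SmoothnessResult:
    """Measure how well ``encoder`` preserves pairwise similarity structure.

    Parameters
    ----------
    stimulus_pairs
        Iterable of ``(x1, x2)`` input pairs (self-pairs are degenerate and
        rejected).  The conventional choice is every (prototype,
        distortion) pair of a stimulus set; see
        :func:`prototype_distortion_pairs`.
    encoder
        Callable mapping a stimulus vector to its representation (an
        :class:`~fmricode.coding.EncoderSpec` works directly).

    Pairs whose representation is constant (e.g. fully saturated deep
    layers) are excluded with a count rather than imputed, since an
    imputed similarity would bias the proportionality statistic.
    """
    in_sims: list[float] = []
    out_sims: list[float] = []
    n_excluded = 0
    for x1, x2 in stimulus_pairs:
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        if x1.shape == x2.shape and np.array_equal(x1, x2):
            raise ValueError("self-pairs are degenerate and must be excluded from the pair set")
        s_in = pearson_similarity(x1, x2)
        try:
            s_out = pearson_similarity(encoder(x1), encoder(x2))
        except DegenerateInputError:
            n_excluded += 1
            continue
        in_sims.append(s_in)
        out_sims.append(s_out)
    return smoothness_from_similarities(in_sims, out_sims, n_excluded=n_excluded)


def gini_sparseness(activations: np.ndarray) -> float:
    """Gini coefficient of absolute activation magnitudes.

    With magnitudes sorted ascending as a_1..a_n,
    ``G = sum_i (2 i - n - 1) a_i / (n * sum_i a_i)``: 0 for perfectly
    uniform activity, (n-1)/n for a one-hot vector.  Scale-invariant.
    """
    a = np.abs(np.asarray(activations, dtype=float).ravel())
    n = a.size
    if n == 0 or not np.any(a > 0):
        raise DegenerateInputError("Gini sparseness undefined for an all-zero vector")
    a = np.sort(a)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) @ a) / (n * a.sum()))
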