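"""Candidate neural coding schemes.

Eleven model encoders probe how much similarity structure survives
increasingly complex transforms: the identity map (vector-space coding),
an elementwise tanh (gain control), a single random weight matrix (matrix
multiplication), a perceptron ``tanh(W x)``, and stacked random tanh
networks of depth 2-8.  Two engineering codes that *destroy* similarity
structure by construction are also provided: two-level full-factorial
design coding (all representations mutually orthogonal) and per-element
SHA-1 hash coding.

All random networks use square ``dim x dim`` weight matrices with
independent standard-normal entries and no bias terms.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd

__all__ = [
    "LayerWeights",
    "EncoderSpec",
    "FactorialDesign",
    "init_network",
    "encode_vector_space",
    "encode_gain_control",
    "encode_matrix_multiplication",
    "encode_perceptron",
    "encode_multilayer",
    "build_factorial_design",
    "encode_factorial",
    "binarize_factors",
    "encode_hash",
    "get_encoder",
    "model_table",
]

STUDY_DEPTH_RANGE = (1, 8)


@dataclass(frozen=True)
class LayerWeights:
    """One fully connected layer: a square standard-normal weight matrix."""

    matrix: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class EncoderSpec:
    """A coding scheme plus its random parameters.

    ``scheme`` is one of ``vector_space``, ``gain_control``,
    ``matrix_multiplication``, ``perceptron``, ``multilayer``.  For
    ``multilayer`` the depth equals the number of weight layers; the
    parameter-free schemes carry no weights.
    """

    scheme: str
    weights: tuple[LayerWeights, ...] = ()

    _VALID = ("vector_space", "gain_control", "matrix_multiplication", "perceptron", "multilayer")

    def __post_init__(self) -> None:
        if self.scheme not in self._VALID:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {self._VALID}")
        n = len(self.weights)
        if self.scheme in ("vector_space", "gain_control") and n != 0:
            raise ValueError(f"{self.scheme} takes no weights")
        if self.scheme in ("matrix_multiplication", "perceptron") and n != 1:
            raise ValueError(f"{self.scheme} takes exactly one weight layer")
        if self.scheme == "multilayer" and n < 1:
            raise ValueError("multilayer needs at least one weight layer")

    @property
    def depth(self) -> int:
        return len(self.weights)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return get_encoder(self)(x)

    def truncated(self, depth: int) -> "EncoderSpec":
        """The first ``depth`` layers of a multilayer stack as a new spec."""
        if depth < 1 or depth > self.depth:
            raise ValueError(f"depth must be in 1..{self.depth}")
        return EncoderSpec(scheme="multilayer", weights=self.weights[:depth])


def init_network(dim: int = 100, depth: int = 8, seed: int | np.random.Generator | None = None) -> EncoderSpec:
    """Initialize a random fully connected tanh network.

    ``depth`` square ``dim x dim`` matrices with independent N(0, 1)
    entries, no biases.  Deterministic given an integer seed.  Depths
    outside 1..8 are allowed but warned about (the study range).
    """
    if dim < 2:
        raise ValueError(f"dim must be >= 2, got {dim}")
    if not (STUDY_DEPTH_RANGE[0] <= depth <= STUDY_DEPTH_RANGE[1]):
        warnings.warn(f"depth {depth} outside the study range {STUDY_DEPTH_RANGE}", stacklevel=2)
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    layers = tuple(
        LayerWeights(matrix=rng.standard_normal((dim, dim)), seed=seed if isinstance(seed, int) else None)
        for _ in range(depth)
    )
    return EncoderSpec(scheme="multilayer", weights=layers)


# ---------------------------------------------------------------------------
# encoders


def encode_vector_space(x: np.ndarray) -> np.ndarray:
    """Identity map: the representation is the stimulus itself."""
    return np.asarray(x, dtype=float)


def encode_gain_control(x: np.ndarray) -> np.ndarray:
    """Elementwise tanh squashing into (-1, 1)."""
    return np.tanh(np.asarray(x, dtype=float))


def encode_matrix_multiplication(x: np.ndarray, w: LayerWeights) -> np.ndarray:
    """Linear map y = W x."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != w.dim:
        raise ValueError(f"stimulus dim {x.shape[-1]} does not match weights dim {w.dim}")
    return x @ w.matrix.T


def encode_perceptron(x: np.ndarray, w: LayerWeights) -> np.ndarray:
    """Single tanh layer: y = tanh(W x)."""
    return np.tanh(encode_matrix_multiplication(x, w))


def encode_multilayer(
    x: np.ndarray, spec: EncoderSpec, *, return_layers: bool = False
) -> np.ndarray | list[np.ndarray]:
    """Stacked tanh layers; the simulated scan reads only the final layer.

    With ``return_layers=True`` the full list of per-layer activations is
    returned for diagnostics (entry ``k`` is the output of layer ``k+1``).
    """
    if spec.scheme != "multilayer":
        raise ValueError(f"expected a multilayer spec, got {spec.scheme}")
    y = np.asarray(x, dtype=float)
    layers = []
    for w in spec.weights:
        y = encode_perceptron(y, w)
        if return_layers:
            layers.append(y)
    return layers if return_layers else y


def get_encoder(spec: EncoderSpec):
    """Uniform callable contract: stimulus vector -> representation vector."""
    if spec.scheme == "vector_space":
        return encode_vector_space
    if spec.scheme == "gain_control":
        return encode_gain_control
    if spec.scheme == "matrix_multiplication":
        return lambda x: encode_matrix_multiplication(x, spec.weights[0])
    if spec.scheme == "perceptron":
        return lambda x: encode_perceptron(x, spec.weights[0])
    return lambda x: encode_multilayer(x, spec)


def model_table(network: EncoderSpec) -> list[tuple[int, str, EncoderSpec]]:
    """The eleven numbered models, sharing one 8-layer stack per network.

    Models 1-4 are vector space, gain control, matrix multiplication (layer
    1 weights) and perceptron (layer 1 weights); models 5-11 are the 2- to
    8-layer truncations of the same stack.
    """
    if network.scheme != "multilayer" or network.depth < 8:
        raise ValueError("model_table needs a multilayer network of depth >= 8")
    w1 = network.weights[0]
    rows = [
        (1, "vector_space", EncoderSpec("vector_space")),
        (2, "gain_control", EncoderSpec("gain_control")),
        (3, "matrix_multiplication", EncoderSpec("matrix_multiplication", (w1,))),
        (4, "perceptron", EncoderSpec("perceptron", (w1,))),
    ]
    for model_id, depth in zip(range(5, 12), range(2, 9)):
        rows.append((model_id, f"{depth}-layer network", network.truncated(depth)))
    return rows


def save_network(spec: EncoderSpec, directory) -> None:
    """Export a weight stack as delimited tables plus a JSON descriptor."""
    import json
    import os

    os.makedirs(directory, exist_ok=True)
    for k, w in enumerate(spec.weights, start=1):
        np.savetxt(os.path.join(directory, f"layer_{k}.tsv"), w.matrix, delimiter="\t")
    descriptor = {
        "scheme": spec.scheme,
        "dim": spec.weights[0].dim if spec.weights else None,
        "depth": spec.depth,
        "seed": spec.weights[0].seed if spec.weights else None,
    }
    with open(os.path.join(directory, "network.json"), "w") as fh:
        json.dump(descriptor, fh, indent=2)


def load_network(directory) -> EncoderSpec:
    """Re-import a weight stack written by :func:`save_network`."""
    import json
    import os

    with open(os.path.join(directory, "network.json")) as fh:
        descriptor = json.load(fh)
    weights = tuple(
        LayerWeights(
            matrix=np.loadtxt(os.path.join(directory, f"layer_{k}.tsv"), delimiter="\t"),
            seed=descriptor.get("seed"),
        )
        for k in range(1, descriptor["depth"] + 1)
    )
    return EncoderSpec(scheme=descriptor["scheme"], weights=weights)


# ---------------------------------------------------------------------------
# factorial design coding


@dataclass(frozen=True)
class FactorialDesign:
    """Two-level full factorial design matrix over ``n_factors`` factors.

    ``matrix`` is the integer ``2^n x 2^n`` array of ±1 with columns for
    the intercept, every main effect and every interaction.  Rows follow
    the standard (Yates) enumeration with the first factor varying
    fastest; columns are ordered by interaction order, then
    lexicographically.  All distinct rows and columns are mutually
    orthogonal, so ``matrix / sqrt(2^n)`` is an orthogonal matrix.
    """

    n_factors: int
    matrix: np.ndarray
    column_labels: tuple[str, ...]

    @property
    def size(self) -> int:
        return 2**self.n_factors

    def normalized(self) -> np.ndarray:
        """Q = matrix / sqrt(2^n); satisfies Q Qᵀ = Qᵀ Q = I."""
        return self.matrix / np.sqrt(self.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.column_labels))


def _factor_names(n: int) -> list[str]:
    if n <= 26:
        return [chr(ord("A") + i) for i in range(n)]
    return [f"F{i + 1}" for i in range(n)]


def build_factorial_design(n_factors: int) -> FactorialDesign:
    """Build the full two-level factorial design matrix.

    Columns: intercept ``I``, main effects, then interactions of growing
    order (AB, AC, BC, ABC for three factors).  ``n_factors`` is limited
    to 12 to keep the 2^n x 2^n matrix desk-scale.
    """
    if not (1 <= n_factors <= 12):
        raise ValueError(f"n_factors must be in 1..12, got {n_factors}")
    names = _factor_names(n_factors)
    # Yates order: first factor alternates fastest.
    levels = np.empty((2**n_factors, n_factors), dtype=int)
    for i, combo in enumerate(product([-1, 1], repeat=n_factors)):
        levels[i] = combo[::-1]  # reversed so the first factor varies fastest
    cols = [np.ones(2**n_factors, dtype=int)]
    labels = ["I"]
    for order in range(1, n_factors + 1):
        for subset in combinations(range(n_factors), order):
            cols.append(np.prod(levels[:, list(subset)], axis=1))
            labels.append("".join(names[i] for i in subset))
    matrix = np.column_stack(cols)
    return FactorialDesign(n_factors=n_factors, matrix=matrix, column_labels=tuple(labels))


def encode_factorial(factors: np.ndarray, design: FactorialDesign | None = None) -> np.ndarray:
    """Represent a ±1 factor setting as its full factorial design row.

    The output of length ``2^n`` contains the intercept and all subset
    products of the factors; representations of distinct settings have
    dot product exactly zero.
    """
    factors = np.asarray(factors)
    if factors.ndim != 1 or not np.all(np.isin(factors, (-1, 1))):
        raise ValueError("factors must be a 1-D vector of +1/-1 entries")
    n = factors.size
    if design is None:
        design = build_factorial_design(n)
    elif design.n_factors != n:
        raise ValueError(f"design has {design.n_factors} factors, input has {n}")
    out = np.empty(design.size, dtype=int)
    out[0] = 1
    idx = 1
    for order in range(1, n + 1):
        for subset in combinations(range(n), order):
            out[idx] = np.prod(factors[list(subset)])
            idx += 1
    return out


def binarize_factors(x: np.ndarray) -> np.ndarray:
    """Sign-binarize a continuous stimulus into ±1 factor levels.

    Extension helper only: the factorial code is defined on discrete ±1
    factor settings, and this map (zero treated as +1) is one documented
    way to push continuous stimuli through it.
    """
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1, -1)


# ---------------------------------------------------------------------------
# hash coding

_HASH_VALUES_PER_DIGEST = 20


def encode_hash(x: np.ndarray) -> np.ndarray:
    """Per-element SHA-1 coding: deterministic but similarity-destroying.

    Each element is serialized to its shortest round-trip decimal string,
    UTF-8 encoded, hashed with SHA-1, and the 20 digest bytes are mapped
    to 20 reals in [-1, 1] via ``byte / 127.5 - 1``.  The output length is
    ``20 * len(x)``.  Any change to an input element scrambles its digest,
    so representations of even near-identical stimuli are uncorrelated.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("hash coding requires finite input values")
    out = np.empty(x.size * _HASH_VALUES_PER_DIGEST)
    for i, v in enumerate(x.ravel()):
        digest = hashlib.sha1(repr(float(v)).encode("utf-8")).digest()
        out[i * _HASH_VALUES_PER_DIGEST : (i + 1) * _HASH_VALUES_PER_DIGEST] = (
            np.frombuffer(digest, dtype=np.uint8) / 127.5 - 1.0
        )
    return out
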