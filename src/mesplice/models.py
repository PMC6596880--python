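"""Maximum-entropy splice-site motif models.

A splice-site model assigns a log2 likelihood-ratio score to a fixed-length
nucleotide motif: 9-mers for donor (5') sites, 23-mers for acceptor (3')
sites. The signal distribution is the maximum-entropy distribution subject
to empirical marginal constraints on subsets of motif positions; the
background distribution describes non-site sequence (per-position base
frequencies, uniform by default). Scores are

    score(x) = log2( P_signal(x) / P_background(x) )

Both distributions are represented as products of factor tables over
position subsets, with positive or negative exponents, which covers all
model families used here: independent per-position models, first-order
Markov chains (the exact maximum-entropy solution under first-order plus
adjacent-pair constraints), and full-joint models fitted by iterative
proportional fitting under arbitrary marginal constraints (enumerable
motif lengths only).

:class:`SpliceSiteModel` follows scikit-learn estimator conventions:
hyper-parameters in ``__init__``, a ``fit`` method taking sequences,
``score_samples`` for log2 likelihood ratios, ``sample`` for generative
draws, and trailing-underscore fitted attributes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._sequences import (
    AmbiguousBaseError,
    MotifLengthError,
    indices_to_seq,
    seq_to_indices,
)

MOTIF_LENGTHS = {"donor": 9, "acceptor": 23}
# Near-invariant intronic dinucleotide: GT at donor offsets 3-4 (first two
# intron bases), AG at acceptor offsets 18-19 (last two intron bases).
CONSENSUS_OFFSETS = {"donor": (3, 4), "acceptor": (18, 19)}
CONSENSUS_BASES = {"donor": "GT", "acceptor": "AG"}

DEFAULT_PROB_FLOOR = 1e-9
_ENUMERABLE_MAX_LENGTH = 12

TABLE_FORMAT_TAG = "mesplice-maxent-tables/1"
MODEL_FORMAT_TAG = "mesplice-model/1"


class TableParseError(ValueError):
    """Malformed or truncated model table file."""


class TableDimensionError(ValueError):
    """Table size inconsistent with its declared position subset."""


# ---------------------------------------------------------------------------
# factored distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Factor:
    """A probability table over a subset of motif positions.

    ``table`` has shape ``(4,)*len(positions)`` with axes ordered as
    ``positions``; ``sign`` is +1 (numerator) or -1 (denominator), the
    latter arising in decomposable chain models.
    """

    positions: tuple[int, ...]
    table: np.ndarray
    sign: int = 1

    def __post_init__(self):
        if self.table.shape != (4,) * len(self.positions):
            raise TableDimensionError(
                f"factor over positions {self.positions} needs shape "
                f"{(4,) * len(self.positions)}, got {self.table.shape}"
            )
        if self.sign not in (-1, 1):
            raise ValueError("factor sign must be +1 or -1")

    def log2_of(self, idx: np.ndarray) -> float:
        return self.sign * float(np.log2(self.table[tuple(idx[list(self.positions)])]))


class FactorDistribution:
    """Product of signed factor tables over motif positions."""

    def __init__(self, length: int, factors: Sequence[Factor]):
        self.length = int(length)
        self.factors = list(factors)
        for f in self.factors:
            if min(f.positions) < 0 or max(f.positions) >= self.length:
                raise TableDimensionError(
                    f"factor positions {f.positions} outside [0, {self.length})"
                )

    def log2p(self, idx: np.ndarray) -> float:
        return sum(f.log2_of(idx) for f in self.factors)

    # -- structure probes (used by the sampler) ----------------------------
    def _is_independent_product(self) -> bool:
        if any(f.sign != 1 for f in self.factors):
            return False
        seen: set[int] = set()
        for f in self.factors:
            if seen.intersection(f.positions):
                return False
            seen.update(f.positions)
        return seen == set(range(self.length))

    def _chain_parts(self):
        """Return (pair_tables, singleton_tables) if this is a first-order
        Markov chain decomposition, else None."""
        pairs = {}
        negs = {}
        for f in self.factors:
            if f.sign == 1 and len(f.positions) == 2 and f.positions[1] == f.positions[0] + 1:
                pairs[f.positions[0]] = f.table
            elif f.sign == -1 and len(f.positions) == 1:
                negs[f.positions[0]] = f.table
            else:
                return None
        if set(pairs) != set(range(self.length - 1)):
            return None
        if set(negs) != set(range(1, self.length - 1)):
            return None
        return pairs, negs

    def dense_log2(self) -> np.ndarray:
        """Full joint log2-probability array, shape (4,)*length."""
        if self.length > _ENUMERABLE_MAX_LENGTH:
            raise ValueError(f"motif length {self.length} is not enumerable")
        out = np.zeros((4,) * self.length)
        for f in self.factors:
            # put factor axes into ascending genomic order, then broadcast
            tab = np.transpose(f.table, np.argsort(f.positions))
            expand = tab.reshape(
                [4 if i in f.positions else 1 for i in range(self.length)]
            )
            out += f.sign * np.log2(expand)
        return out

    def total_probability(self) -> float:
        return float(np.exp2(self.dense_log2()).sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n motif index vectors, shape (n, length)."""
        if self._is_independent_product():
            out = np.empty((n, self.length), dtype=np.intp)
            for f in sorted(self.factors, key=lambda f: f.positions):
                k = len(f.positions)
                flat = f.table.reshape(-1)
                draws = rng.choice(flat.size, size=n, p=flat / flat.sum())
                sub = np.stack(np.unravel_index(draws, (4,) * k), axis=1)
                out[:, list(f.positions)] = sub
            return out
        chain = self._chain_parts()
        if chain is not None:
            pairs, _ = chain
            out = np.empty((n, self.length), dtype=np.intp)
            p0 = pairs[0].sum(axis=1)
            out[:, 0] = rng.choice(4, size=n, p=p0 / p0.sum())
            for i in range(self.length - 1):
                cond = pairs[i] / pairs[i].sum(axis=1, keepdims=True)
                u = rng.random(n)
                cum = np.cumsum(cond, axis=1)
                out[:, i + 1] = (u[:, None] > cum[out[:, i]]).sum(axis=1)
            return out
        # generic fallback: enumerate the joint
        probs = np.exp2(self.dense_log2()).reshape(-1)
        probs = probs / probs.sum()
        draws = rng.choice(probs.size, size=n, p=probs)
        return np.stack(np.unravel_index(draws, (4,) * self.length), axis=1)


def uniform_background(length: int) -> FactorDistribution:
    return FactorDistribution(
        length, [Factor((i,), np.full(4, 0.25)) for i in range(length)]
    )


# ---------------------------------------------------------------------------
# marginal constraints and fitting
# ---------------------------------------------------------------------------

@dataclass
class MarginalConstraintSet:
    """Empirical joint-frequency targets over position subsets.

    The maximum-entropy fit matches the model's marginals to each target
    table within ``tolerance`` (max absolute deviation).
    """

    motif_length: int
    constraints: list[tuple[tuple[int, ...], np.ndarray]] = field(default_factory=list)
    tolerance: float = 1e-6

    def validate(self) -> None:
        for positions, table in self.constraints:
            if any(p < 0 or p >= self.motif_length for p in positions):
                raise TableDimensionError(
                    f"constraint positions {positions} outside [0, {self.motif_length})"
                )
            if table.shape != (4,) * len(positions):
                raise TableDimensionError(
                    f"constraint table over {positions} has shape {table.shape}"
                )
            if abs(float(table.sum()) - 1.0) > 1e-9:
                raise ValueError(
                    f"constraint table over {positions} sums to {table.sum()!r}, not 1"
                )


def constraint_subsets(length: int, scheme) -> list[tuple[int, ...]]:
    """Expand a constraint scheme name into position subsets."""
    if not isinstance(scheme, str):
        return [tuple(sorted(s)) for s in scheme]
    singles = [(i,) for i in range(length)]
    if scheme == "first_order":
        return singles
    if scheme == "adjacent_pairs":
        return singles + [(i, i + 1) for i in range(length - 1)]
    if scheme == "all_pairs":
        return singles + [
            (i, j) for i in range(length) for j in range(i + 1, length)
        ]
    raise ValueError(f"unknown constraint scheme {scheme!r}")


def empirical_marginals(
    X: np.ndarray,
    subsets: Iterable[tuple[int, ...]],
    floor: float = DEFAULT_PROB_FLOOR,
    tolerance: float = 1e-6,
) -> MarginalConstraintSet:
    """Empirical joint frequencies of encoded sequences over each subset.

    Zero cells are floored at ``floor`` then renormalized so downstream
    ratios stay finite.
    """
    length = X.shape[1]
    cons = []
    for subset in subsets:
        k = len(subset)
        ranks = np.zeros(X.shape[0], dtype=np.int64)
        for p in subset:
            ranks = ranks * 4 + X[:, p]
        counts = np.bincount(ranks, minlength=4 ** k).astype(float)
        table = counts / counts.sum()
        table = np.maximum(table, floor)
        table = table / table.sum()
        cons.append((tuple(subset), table.reshape((4,) * k)))
    out = MarginalConstraintSet(length, cons, tolerance)
    out.validate()
    return out


def _marginal_of(P: np.ndarray, positions: tuple[int, ...]) -> np.ndarray:
    """Marginal table over `positions` (which must be ascending)."""
    if tuple(sorted(positions)) != tuple(positions):
        raise ValueError("positions must be ascending")
    axes = tuple(i for i in range(P.ndim) if i not in positions)
    return P.sum(axis=axes)


def _ipf_fit(length, constraints, tolerance, max_iter):
    """Iterative proportional fitting of the full joint (enumerable lengths).

    Multiplicative updates by the ratio of target to model marginal, the
    classical iterative-scaling fixed point for maximum entropy under
    marginal constraints.
    """
    if length > _ENUMERABLE_MAX_LENGTH:
        raise ValueError(
            f"full-joint fitting requires an enumerable motif (length <= "
            f"{_ENUMERABLE_MAX_LENGTH}); got {length}"
        )
    P = np.full((4,) * length, 4.0 ** -length)
    max_dev = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for positions, target in constraints:
            m = _marginal_of(P, positions)
            ratio = target / np.maximum(m, 1e-300)
            expand = ratio.reshape(
                [4 if i in positions else 1 for i in range(length)]
            )
            P = P * expand
        P = P / P.sum()
        max_dev = max(
            float(np.abs(_marginal_of(P, pos) - tgt).max())
            for pos, tgt in constraints
        )
        if max_dev < tolerance:
            break
    return P, max_dev < tolerance, n_iter, max_dev


def _sorted_constraints(cset: MarginalConstraintSet):
    """Canonicalize constraint subsets to ascending position order."""
    out = []
    for positions, table in cset.constraints:
        order = np.argsort(positions)
        sorted_pos = tuple(int(x) for x in np.asarray(positions)[order])
        out.append((sorted_pos, np.transpose(table, order)
                    if len(positions) > 1 else table))
    return out


def _chain_factors(length, constraints) -> list[Factor]:
    """Closed-form maximum entropy for first-order + adjacent-pair
    constraints: a first-order Markov chain,
    P(x) = prod_i p(x_i, x_{i+1}) / prod_{interior i} p(x_i),
    with singleton marginals taken from the pair tables for exact
    consistency."""
    pairs = {pos: tab for pos, tab in constraints if len(pos) == 2}
    needed = {(i, i + 1) for i in range(length - 1)}
    if set(pairs) != needed:
        raise ValueError(
            "chain fitting needs exactly the adjacent-pair constraints; "
            f"got {sorted(pairs)}"
        )
    factors = [Factor((i, i + 1), pairs[(i, i + 1)]) for i in range(length - 1)]
    for i in range(1, length - 1):
        # marginal of position i from the pair on its left
        factors.append(Factor((i,), pairs[(i - 1, i)].sum(axis=0), sign=-1))
    return factors


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class SpliceSiteModel(BaseEstimator):
    """Maximum-entropy donor/acceptor splice-site scorer.

    Parameters
    ----------
    site_type : {"donor", "acceptor"}
        Fixes the motif length (9 or 23) and the consensus dinucleotide
        offsets (GT at 3-4, AG at 18-19).
    constraints : str or sequence of position tuples
        Marginal constraints for the signal fit. ``"first_order"``,
        ``"adjacent_pairs"`` and ``"all_pairs"`` expand to the obvious
        subsets; explicit subsets are allowed for enumerable motifs.
        Defaults: donor ``"all_pairs"`` (fitted by iterative proportional
        fitting on the full 4^9 joint), acceptor ``"adjacent_pairs"``
        (exact closed-form Markov chain; the 4^23 joint is not enumerable).
    tolerance : float
        Maximum absolute marginal deviation accepted as converged.
    max_iter : int
        Iterative-scaling sweep limit.
    prob_floor : float
        Floor applied to empirical zero cells so scores stay finite.

    Attributes
    ----------
    signal_ : FactorDistribution
    background_ : FactorDistribution
    converged_ : bool
    n_iter_ : int
    max_marginal_dev_ : float
    """

    def __init__(
        self,
        site_type: str = "donor",
        constraints=None,
        tolerance: float = 1e-6,
        max_iter: int = 1000,
        prob_floor: float = DEFAULT_PROB_FLOOR,
    ):
        self.site_type = site_type
        self.constraints = constraints
        self.tolerance = tolerance
        self.max_iter = max_iter
        self.prob_floor = prob_floor

    # -- fixed geometry -----------------------------------------------------
    @property
    def motif_length(self) -> int:
        if self.site_type not in MOTIF_LENGTHS:
            raise ValueError(f"unknown site_type {self.site_type!r}")
        return MOTIF_LENGTHS[self.site_type]

    @property
    def consensus_offsets(self) -> tuple[int, int]:
        return CONSENSUS_OFFSETS[self.site_type]

    # -- construction without fitting ----------------------------------------
    @classmethod
    def from_components(cls, site_type, signal: FactorDistribution,
                        background: FactorDistribution) -> "SpliceSiteModel":
        model = cls(site_type=site_type)
        if signal.length != model.motif_length or background.length != model.motif_length:
            raise TableDimensionError(
                f"{site_type} components must have length {model.motif_length}"
            )
        model.signal_ = signal
        model.background_ = background
        model.converged_ = True
        model.n_iter_ = 0
        model.max_marginal_dev_ = 0.0
        return model

    @classmethod
    def from_pwm(cls, site_type, pwm, background_freqs=None,
                 prob_floor: float = DEFAULT_PROB_FLOOR) -> "SpliceSiteModel":
        """Independent per-position model from a position weight matrix
        (rows = motif positions, columns = A,C,G,T probabilities)."""
        pwm = np.asarray(pwm, dtype=float)
        length = MOTIF_LENGTHS[site_type]
        if pwm.shape != (length, 4):
            raise TableDimensionError(
                f"{site_type} PWM must have shape ({length}, 4), got {pwm.shape}"
            )
        rows = np.maximum(pwm, prob_floor)
        rows = rows / rows.sum(axis=1, keepdims=True)
        signal = FactorDistribution(
            length, [Factor((i,), rows[i]) for i in range(length)]
        )
        if background_freqs is None:
            background = uniform_background(length)
        else:
            bg = np.maximum(np.asarray(background_freqs, dtype=float), prob_floor)
            bg = bg / bg.sum()
            background = FactorDistribution(
                length, [Factor((i,), bg) for i in range(length)]
            )
        return cls.from_components(site_type, signal, background)

    # -- fitting --------------------------------------------------------------
    def _default_scheme(self) -> str:
        return "all_pairs" if self.site_type == "donor" else "adjacent_pairs"

    def _encode(self, seqs) -> np.ndarray:
        if len(seqs) == 0:
            raise ValueError("empty training set")
        return np.stack([seq_to_indices(s, self.motif_length) for s in seqs])

    def _fit_component(self, X: np.ndarray, scheme) -> tuple[FactorDistribution, bool, int, float]:
        length = self.motif_length
        subsets = constraint_subsets(length, scheme)
        cset = empirical_marginals(X, subsets, floor=self.prob_floor,
                                   tolerance=self.tolerance)
        return self._fit_from_constraints(cset)

    def _fit_from_constraints(self, cset: MarginalConstraintSet):
        cset.validate()
        length = self.motif_length
        cons = _sorted_constraints(cset)
        subsets = {pos for pos, _ in cons}
        if all(len(pos) == 1 for pos in subsets) and subsets == {(i,) for i in range(length)}:
            # maximum entropy under first-order constraints is the product
            # of marginals — closed form
            factors = [Factor(pos, tab) for pos, tab in cons]
            return FactorDistribution(length, factors), True, 1, 0.0
        pair_part = {pos for pos in subsets if len(pos) == 2}
        if pair_part == {(i, i + 1) for i in range(length - 1)} and all(
            len(pos) <= 2 for pos in subsets
        ):
            factors = _chain_factors(length, cons)
            return FactorDistribution(length, factors), True, 1, 0.0
        P, converged, n_iter, max_dev = _ipf_fit(
            length, cons, cset.tolerance, self.max_iter
        )
        if not converged:
            warnings.warn(
                f"iterative scaling did not converge in {self.max_iter} sweeps; "
                f"max marginal deviation {max_dev:.3g}",
                stacklevel=2,
            )
        dist = FactorDistribution(length, [Factor(tuple(range(length)), P)])
        return dist, converged, n_iter, max_dev

    def fit(self, X, y=None, background=None):
        """Fit signal (and optionally background) components.

        Parameters
        ----------
        X : sequence of motif-length nucleotide strings
            Splice-site training sequences.
        background : sequence of motif-length strings, optional
            Background training sequences; fitted with first-order
            constraints. Uniform background when omitted.
        """
        Xi = self._encode(X)
        if Xi.shape[0] < 50:
            warnings.warn(
                f"only {Xi.shape[0]} training sequences; marginal estimates "
                "will be noisy", stacklevel=2,
            )
        scheme = self.constraints if self.constraints is not None else self._default_scheme()
        self.signal_, self.converged_, self.n_iter_, self.max_marginal_dev_ = (
            self._fit_component(Xi, scheme)
        )
        if background is not None and len(background) > 0:
            Bi = self._encode(background)
            self.background_, _, _, _ = self._fit_component(Bi, "first_order")
        else:
            self.background_ = uniform_background(self.motif_length)
        return self

    # -- scoring --------------------------------------------------------------
    def score_seq(self, seq: str) -> float:
        """log2 likelihood ratio of a single motif-length sequence."""
        self._check_fitted()
        idx = seq_to_indices(seq, self.motif_length)
        return self.signal_.log2p(idx) - self.background_.log2p(idx)

    def score_samples(self, X) -> np.ndarray:
        return np.array([self.score_seq(s) for s in X])

    def sample(self, n_samples: int, random_state=None) -> list[str]:
        """Draw i.i.d. motifs from the signal distribution."""
        self._check_fitted()
        if n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {n_samples}")
        rng = np.random.default_rng(random_state)
        idx = self.signal_.sample(n_samples, rng)
        return [indices_to_seq(row) for row in idx]

    def _check_fitted(self):
        if not hasattr(self, "signal_"):
            raise AttributeError(
                "model is not fitted; call fit(), from_pwm() or load tables"
            )

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()

        def dump(dist):
            return [
                {
                    "positions": list(f.positions),
                    "sign": f.sign,
                    "values": f.table.reshape(-1).tolist(),
                }
                for f in dist.factors
            ]

        return {
            "format": MODEL_FORMAT_TAG,
            "site_type": self.site_type,
            "motif_length": self.motif_length,
            "consensus_offsets": list(self.consensus_offsets),
            "signal": dump(self.signal_),
            "background": dump(self.background_),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SpliceSiteModel":
        if doc.get("format") != MODEL_FORMAT_TAG:
            raise TableParseError(
                f"unrecognized model format tag {doc.get('format')!r}"
            )
        site_type = doc["site_type"]
        length = MOTIF_LENGTHS[site_type]
        if doc.get("motif_length") != length:
            raise TableDimensionError(
                f"{site_type} model declares motif_length {doc.get('motif_length')}"
            )

        def load(entries):
            factors = []
            for e in entries:
                pos = tuple(e["positions"])
                vals = np.asarray(e["values"], dtype=float)
                if vals.size != 4 ** len(pos):
                    raise TableDimensionError(
                        f"factor over {pos} has {vals.size} values, "
                        f"expected {4 ** len(pos)}"
                    )
                factors.append(Factor(pos, vals.reshape((4,) * len(pos)), e.get("sign", 1)))
            return FactorDistribution(length, factors)

        return cls.from_components(site_type, load(doc["signal"]), load(doc["background"]))

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path) -> "SpliceSiteModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# table-directory layout (factorized value files + manifest)
# ---------------------------------------------------------------------------

def _read_value_file(path: Path, n_expected: int) -> np.ndarray:
    """One probability per line, lexicographic ACGT order."""
    values = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise TableParseError(f"{path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            values.append(float(line.split()[-1]))
        except ValueError:
            raise TableParseError(
                f"{path}:{lineno}: cannot parse value {line!r}"
            ) from None
    if len(values) != n_expected:
        raise TableParseError(
            f"{path}: expected {n_expected} values, found {len(values)} "
            "(truncated or wrong table?)"
        )
    return np.asarray(values)


def _load_component(manifest_dir: Path, entries, length: int) -> FactorDistribution:
    factors = []
    for e in entries:
        pos = tuple(e["positions"])
        if any(p < 0 or p >= length for p in pos):
            raise TableDimensionError(
                f"factor positions {pos} outside motif of length {length}"
            )
        vals = _read_value_file(manifest_dir / e["file"], 4 ** len(pos))
        table = vals.reshape((4,) * len(pos))
        total = float(table.sum())
        if e.get("sign", 1) == 1 and abs(total - 1.0) > 1e-6:
            raise TableParseError(
                f"{manifest_dir / e['file']}: factor over {pos} sums to "
                f"{total!r}, not 1"
            )
        factors.append(Factor(pos, table, e.get("sign", 1)))
    return FactorDistribution(length, factors)


def load_model_tables(manifest_path) -> SpliceSiteModel:
    """Load one model from a manifest + value-file table directory."""
    manifest_path = Path(manifest_path)
    try:
        doc = json.loads(manifest_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise TableParseError(f"{manifest_path}: {exc}") from exc
    if doc.get("format") != TABLE_FORMAT_TAG:
        raise TableParseError(
            f"{manifest_path}: unrecognized format tag {doc.get('format')!r}"
        )
    site_type = doc.get("site_type")
    if site_type not in MOTIF_LENGTHS:
        raise TableParseError(f"{manifest_path}: bad site_type {site_type!r}")
    length = MOTIF_LENGTHS[site_type]
    base = manifest_path.parent
    signal = _load_component(base, doc["signal_factors"], length)
    background = _load_component(base, doc["background_factors"], length)
    return SpliceSiteModel.from_components(site_type, signal, background)


def load_reference_tables(donor_table_path, acceptor_table_path):
    """Load donor and acceptor models from their table manifests."""
    donor = load_model_tables(donor_table_path)
    acceptor = load_model_tables(acceptor_table_path)
    if donor.site_type != "donor":
        raise TableParseError(f"{donor_table_path}: not a donor table set")
    if acceptor.site_type != "acceptor":
        raise TableParseError(f"{acceptor_table_path}: not an acceptor table set")
    return donor, acceptor


def save_model_tables(model: SpliceSiteModel, directory, name: str | None = None) -> Path:
    """Serialize a model into the manifest + value-file layout.

    Returns the manifest path. Each factor's probabilities are written one
    per line in lexicographic ACGT order, full precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or model.site_type
    doc = {
        "format": TABLE_FORMAT_TAG,
        "site_type": model.site_type,
        "motif_length": model.motif_length,
        "consensus_offsets": list(model.consensus_offsets),
        "signal_factors": [],
        "background_factors": [],
    }
    for key, dist in (("signal_factors", model.signal_),
                      ("background_factors", model.background_)):
        for i, f in enumerate(dist.factors):
            fname = f"{name}_{key.split('_')[0]}_{i}.tab"
            lines = "\n".join(format(float(v), ".17g")
                              for v in f.table.reshape(-1)) + "\n"
            (directory / fname).write_text(lines)
            doc[key].append(
                {"positions": list(f.positions), "sign": f.sign, "file": fname}
            )
    manifest = directory / f"{name}_manifest.json"
    manifest.write_text(json.dumps(doc, indent=1))
    return manifest


__all__ = [
    "SpliceSiteModel",
    "FactorDistribution",
    "Factor",
    "MarginalConstraintSet",
    "empirical_marginals",
    "constraint_subsets",
    "uniform_background",
    "load_reference_tables",
    "load_model_tables",
    "save_model_tables",
    "AmbiguousBaseError",
    "MotifLengthError",
    "TableParseError",
    "TableDimensionError",
    "MOTIF_LENGTHS",
    "CONSENSUS_OFFSETS",
    "CONSENSUS_BASES",
]
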