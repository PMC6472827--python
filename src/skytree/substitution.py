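"""Reversible nucleotide substitution models indexed by six-digit codes.

A model code assigns each of the six exchange rates (alphabetical pair
order A-C, A-G, A-T, C-G, C-T, G-T) to a group; e.g. ``121121`` is HKY
(transitions A-G and C-T share one group, transversions the other) and
``111111`` is JC69/F81.  Codes are kept in restricted-growth (canonical)
form: the first digit is 1 and each digit exceeds the running maximum of
its predecessors by at most one.  The set of all canonical codes is in
bijection with the set partitions of the six rates (203 = Bell(6)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "PAIR_ORDER",
    "TRANSITION_POSITIONS",
    "ModelCodeError",
    "canonical_code",
    "is_canonical",
    "enumerate_model_set",
    "split_neighbors",
    "merge_neighbors",
    "SiteModel",
    "RateMatrix",
    "build_rate_matrix",
    "transition_probabilities",
    "discrete_gamma_rates",
]

PAIR_ORDER = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))
# 0-based positions of the two transitions (A<->G, C<->T) in PAIR_ORDER
TRANSITION_POSITIONS = (1, 4)
_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class ModelCodeError(ValueError):
    pass


def canonical_code(grouping) -> str:
    """Relabel a 6-element grouping by order of first appearance.

    >>> canonical_code((9, 7, 9, 9, 7, 9))
    '121121'
    """
    grouping = tuple(grouping)
    if len(grouping) != 6:
        raise ModelCodeError(f"expected 6 group ids, got {len(grouping)}")
    if any((not float(g).is_integer()) or g < 1 for g in grouping):
        raise ModelCodeError(f"group ids must be positive integers: {grouping}")
    relabel: dict[int, int] = {}
    out = []
    for g in grouping:
        if g not in relabel:
            relabel[g] = len(relabel) + 1
        out.append(relabel[g])
    if any(v > 9 for v in out):  # cannot happen with 6 rates
        raise ModelCodeError("too many groups")
    return "".join(str(v) for v in out)


def is_canonical(code: str) -> bool:
    try:
        return canonical_code(tuple(int(c) for c in code)) == code and len(code) == 6
    except (ModelCodeError, ValueError):
        return False


def _groups(code: str) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for pos, ch in enumerate(code):
        groups.setdefault(int(ch), []).append(pos)
    return groups


def _mixes_ti_tv(code: str) -> bool:
    for members in _groups(code).values():
        has_ti = any(p in TRANSITION_POSITIONS for p in members)
        has_tv = any(p not in TRANSITION_POSITIONS for p in members)
        if has_ti and has_tv:
            return True
    return False


def enumerate_model_set(restriction: str = "all_reversible") -> frozenset[str]:
    """All canonical codes, optionally excluding transition/transversion
    sharing (JC69/F81's ``111111`` is re-admitted as the sole exception)."""
    codes = set()
    for parts in _restricted_growth_strings(6):
        codes.add("".join(str(p) for p in parts))
    if restriction == "all_reversible":
        return frozenset(codes)
    if restriction == "no_ti_tv_sharing":
        kept = {c for c in codes if not _mixes_ti_tv(c)}
        kept.add("111111")
        return frozenset(kept)
    raise ValueError(f"unknown restriction {restriction!r}")


def _restricted_growth_strings(n: int):
    def rec(prefix: list[int], maxi: int):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in range(1, maxi + 2):
            yield from rec(prefix + [v], max(maxi, v))

    yield from rec([1], 1)


def split_neighbors(code: str, model_set: frozenset[str]) -> list[str]:
    """Codes reachable by splitting one group into two, within model_set."""
    out = set()
    groups = _groups(code)
    for gid, members in groups.items():
        if len(members) < 2:
            continue
        for k in range(1, len(members)):
            for moved in itertools.combinations(members[1:], k):
                digits = [int(c) for c in code]
                new_gid = max(digits) + 1
                for pos in moved:
                    digits[pos] = new_gid
                cand = canonical_code(digits)
                if cand in model_set:
                    out.add(cand)
    return sorted(out)


def merge_neighbors(code: str, model_set: frozenset[str]) -> list[str]:
    """Codes reachable by merging two groups, within model_set."""
    out = set()
    gids = sorted(_groups(code))
    for g1, g2 in itertools.combinations(gids, 2):
        digits = [g1 if int(c) == g2 else int(c) for c in code]
        cand = canonical_code(digits)
        if cand in model_set:
            out.add(cand)
    return sorted(out)


# ---------------------------------------------------------------------------
# Site model
# ---------------------------------------------------------------------------


@dataclass
class SiteModel:
    """Substitution model + across-site rate heterogeneity.

    ``group_rates`` holds one positive relative rate per distinct digit of
    ``code`` (identifiable up to scale; the generator is renormalized to
    mean rate 1 regardless).  Indicator flags mirror the three averaged
    model dimensions: unequal frequencies, gamma rate variation, and a
    nonzero proportion of invariable sites.
    """

    code: str = "111111"
    group_rates: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    base_freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    freqs_equal: bool = True
    gamma_shape: float = 1.0
    use_gamma: bool = False
    n_categories: int = 4
    p_inv: float = 0.0
    use_inv: bool = False

    def __post_init__(self) -> None:
        if not is_canonical(self.code):
            raise ModelCodeError(f"non-canonical model code {self.code!r}")
        self.group_rates = np.asarray(self.group_rates, dtype=float)
        n_groups = max(int(c) for c in self.code)
        if self.group_rates.shape != (n_groups,):
            raise ValueError(
                f"code {self.code} needs {n_groups} group rates, "
                f"got {self.group_rates.shape}"
            )
        if np.any(self.group_rates <= 0):
            raise ValueError("group rates must be positive")
        if self.freqs_equal:
            self.base_freqs = np.full(4, 0.25)
        else:
            self.base_freqs = np.asarray(self.base_freqs, dtype=float)
            if np.any(self.base_freqs <= 0) or abs(self.base_freqs.sum() - 1) > 1e-9:
                raise ValueError("base frequencies must be positive and sum to 1")
        if not self.use_inv:
            self.p_inv = 0.0
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.use_gamma and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    @property
    def relative_rates(self) -> np.ndarray:
        """The six exchange rates implied by code + group rates."""
        return np.array([self.group_rates[int(c) - 1] for c in self.code])

    def category_rates(self) -> np.ndarray:
        if not self.use_gamma:
            return np.array([1.0])
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def with_(self, **kw) -> "SiteModel":
        return replace(self, **kw)


@dataclass
class RateMatrix:
    """Normalized reversible generator with its stationary frequencies."""

    Q: np.ndarray
    pi: np.ndarray
    _eig: tuple | None = None

    def eigensystem(self):
        """Symmetrized eigendecomposition, computed once and cached."""
        if self._eig is None:
            sqrt_pi = np.sqrt(self.pi)
            S = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
            S = 0.5 * (S + S.T)  # enforce exact symmetry
            w, U = np.linalg.eigh(S)
            left = U.T * sqrt_pi[None, :]
            right = U / sqrt_pi[:, None]
            self._eig = (w, right, left)
        return self._eig

    def transition_probabilities(self, t: float) -> np.ndarray:
        return transition_probabilities(self, t)


def build_rate_matrix(model: SiteModel) -> RateMatrix:
    """Q_ij = r_ij * pi_j (i != j), normalized to mean rate 1."""
    rates = model.relative_rates
    pi = model.base_freqs
    Q = np.zeros((4, 4))
    for k, (a, b) in enumerate(PAIR_ORDER):
        i, j = _NUC_INDEX[a], _NUC_INDEX[b]
        Q[i, j] = rates[k] * pi[j]
        Q[j, i] = rates[k] * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    if mu <= 0:
        raise ValueError("degenerate rate matrix")
    return RateMatrix(Q / mu, pi)


def transition_probabilities(Q: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via the reversible (symmetrized) eigendecomposition."""
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"time must be finite and >= 0, got {t}")
    w, right, left = Q.eigensystem()
    P = (right * np.exp(w * t)[None, :]) @ left
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def discrete_gamma_rates(shape: float, ncat: int) -> np.ndarray:
    """Mean-of-bin discrete gamma category rates (mixture mean exactly 1).

    The unit-mean gamma is cut at equal-probability quantiles; each
    category's rate is the conditional mean within its bin, computed with
    the incomplete-gamma identity E[X; X<q] = P(shape+1, q*shape)/1.
    """
    if not np.isfinite(shape) or shape <= 0:
        raise ValueError(f"gamma shape must be positive, got {shape}")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return np.array([1.0])
    edges = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=shape, scale=1.0 / shape)
    cum = gammainc(shape + 1, np.concatenate([[0.0], edges * shape, [np.inf]]))
    rates = ncat * np.diff(cum)
    return rates / rates.mean()  # exact unit mean despite roundoff
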