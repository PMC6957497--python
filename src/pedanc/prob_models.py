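"""Closed-form probability models for ancestry-call errors in pedigrees.

The setting is a two-way admixed population (ancestral proportion ``lamb``
of population-A ancestry, ``tau`` generations since admixture). Along the
genetic map, each haploid ancestry track is a two-state Markov chain whose
switch probability over d Morgans is 1 - exp(-d*tau); diploid dosages are
the sum of two independent tracks. Ancestry calls made by upstream software
are modelled as the truth with each *allele* flipped independently at rate
``epsilon``.

This module provides:

* haploid/diploid transition matrices and the per-call inference matrix;
* the expected dosage error rate E|Y-X| (two variants, see
  :func:`expected_dosage_error`);
* expected per-locus Mendelian-error rates for nuclear families
  (closed-form quadratic polynomials in epsilon), together with an exact
  enumeration and a Monte-Carlo oracle for the same single-error-per-locus
  mechanism, used to audit the polynomials;
* the method-of-moments estimator of epsilon from observed Mendelian-error
  counts;
* the Poisson probability of two or more crossovers in a short window,
  which motivates treating short double crossovers as errors.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .pedigree import FamilyType

__all__ = [
    "ErrorModelParams",
    "TransitionMatrices",
    "MendelianRateModel",
    "haploid_transition",
    "diploid_transition",
    "transition_matrices",
    "inference_matrix",
    "inference_prob",
    "expected_dosage_error",
    "expected_mendelian_rate",
    "exact_mendelian_rate",
    "mendelian_rate_mc",
    "estimate_epsilon",
    "estimate_lambda",
    "double_crossover_prob",
]


@dataclass(frozen=True)
class ErrorModelParams:
    """Allelic error rate, admixture proportion and admixture age.

    tau defaults to 8 generations, a standard value for African-American
    admixture; lamb is typically estimated as the sample-average
    population-A ancestry proportion (about 0.8 in that setting).
    """

    epsilon: float
    lamb: float
    tau: float = 8.0

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon must be in [0, 0.5), got {self.epsilon}")
        if not 0 < self.lamb < 1:
            raise ValueError(f"lamb must be in (0, 1), got {self.lamb}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


class DosageErrorVariant(str, enum.Enum):
    LITERAL = "literal"
    FLIP_MODEL = "flip_model"


def haploid_transition(d: float, tau: float, lamb: float) -> np.ndarray:
    """2x2 allele-ancestry transition matrix over d Morgans.

    P(l|k) = exp(-d*tau)*1[l==k] + (1-exp(-d*tau))*pi_l with stationary
    weights pi = (1-lamb, lamb). Rows are the source state k in {0,1}.
    """
    if d < 0:
        raise ValueError(f"genetic distance must be >= 0, got {d}")
    stay = math.exp(-d * tau)
    pi = np.array([1 - lamb, lamb])
    return stay * np.eye(2) + (1 - stay) * pi[None, :]


def diploid_transition(d: float, tau: float, lamb: float) -> np.ndarray:
    """3x3 dosage transition matrix: two independent haploid chains
    projected from ordered allele pairs onto dosages {0,1,2}."""
    T = haploid_transition(d, tau, lamb)
    M = np.empty((3, 3))
    # dosage 0 = alleles (0,0); dosage 2 = (1,1); dosage 1 = one of each
    M[0] = [T[0, 0] ** 2, 2 * T[0, 0] * T[0, 1], T[0, 1] ** 2]
    M[2] = [T[1, 0] ** 2, 2 * T[1, 0] * T[1, 1], T[1, 1] ** 2]
    M[1] = [
        T[0, 0] * T[1, 0],
        T[0, 0] * T[1, 1] + T[0, 1] * T[1, 0],
        T[0, 1] * T[1, 1],
    ]
    return M


@dataclass(frozen=True)
class TransitionMatrices:
    """Haploid and diploid transition matrices for one inter-marker gap."""

    haploid: np.ndarray
    diploid: np.ndarray
    distance_M: float


def transition_matrices(d: float, tau: float, lamb: float) -> TransitionMatrices:
    return TransitionMatrices(
        haploid=haploid_transition(d, tau, lamb),
        diploid=diploid_transition(d, tau, lamb),
        distance_M=d,
    )


def dosage_stationary(lamb: float) -> np.ndarray:
    """Binomial(2, lamb) marginal of a diploid dosage."""
    return np.array([(1 - lamb) ** 2, 2 * lamb * (1 - lamb), lamb**2])


def inference_matrix(epsilon: float) -> np.ndarray:
    """3x3 matrix P(Y=y | X=x) under independent per-allele flips at rate
    epsilon; rows are the true dosage x."""
    if not 0 <= epsilon < 0.5:
        raise ValueError(f"epsilon must be in [0, 0.5), got {epsilon}")
    e = epsilon
    return np.array(
        [
            [(1 - e) ** 2, 2 * e * (1 - e), e**2],
            [e * (1 - e), (1 - e) ** 2 + e**2, e * (1 - e)],
            [e**2, 2 * e * (1 - e), (1 - e) ** 2],
        ]
    )


def inference_prob(y: int, x: int, epsilon: float) -> float:
    """P(observed dosage y | true dosage x)."""
    if x not in (0, 1, 2) or y not in (0, 1, 2):
        raise ValueError(f"dosages must be in {{0,1,2}}, got x={x}, y={y}")
    return float(inference_matrix(epsilon)[x, y])


def expected_dosage_error(
    epsilon: float,
    lamb: float,
    variant: DosageErrorVariant | str = DosageErrorVariant.FLIP_MODEL,
) -> float:
    """Expected dosage error rate err = E|Y - X|.

    ``flip_model`` (default) evaluates E|Y-X| exactly under the per-allele
    flip model and the Binomial(2, lamb) marginal of X:
    2*eps*(1-eps) + 2*eps^2*[lamb^2 + (1-lamb)^2]. ``literal`` returns the
    commonly quoted closed form, which carries the eps^2 term without the
    factor 2; the two differ by at most eps^2.
    """
    variant = DosageErrorVariant(variant)
    e, s = epsilon, lamb**2 + (1 - lamb) ** 2
    if variant is DosageErrorVariant.LITERAL:
        return 2 * e * (1 - e) + e**2 * s
    P = inference_matrix(e)
    px = dosage_stationary(lamb)
    diff = np.abs(np.arange(3)[:, None] - np.arange(3)[None, :])
    return float(px @ (P * diff).sum(axis=1))


@dataclass(frozen=True)
class MendelianRateModel:
    """A nuclear family shape for Mendelian-error-rate calculations."""

    family_type: FamilyType
    m: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")


def _me_rate_coeffs(model: MendelianRateModel, lamb: float) -> tuple[float, float]:
    """Coefficients (b, a) of the closed-form expected per-locus
    Mendelian-error rate a*eps^2 + b*eps for a nuclear family."""
    m, lam = model.m, lamb
    ll = lam * (1 - lam)
    if model.family_type is FamilyType.TWO_PARENT:
        a = (
            2
            - m
            + (4 * m - 12 + 0.5 ** (m - 2)) * ll
            - (6 * m - 16 * 0.75**m + 0.5 ** (m - 3)) * ll**2
        )
        b = (
            2 * m
            + (8 - 6 * m - 0.5 ** (m - 3)) * ll
            + (4 * m - 16 * 0.75**m + 0.5 ** (m - 4)) * ll**2
        )
    else:
        c = 2 * ll * (2 - (1 - lam / 2) ** m - (0.5 + lam / 2) ** m + m / 2)
        quad = lam * (1 + lam - (1 - lam) ** m) + (1 - lam) ** 2 * (
            2 - lam + lam**m
        )
        # 2*eps*(1-eps)*c + eps^2*quad == c*eps + (quad - c)*eps^2
        b = c
        a = quad - c
    return b, a


def expected_mendelian_rate(
    model: MendelianRateModel, epsilon: float, lamb: float
) -> float:
    """Closed-form expected number of Mendelian-inconsistent loci per locus
    for one nuclear family (quadratic in epsilon, derived under the
    one-erring-member-per-locus assumption)."""
    if not 0 <= epsilon < 0.5:
        raise ValueError(f"epsilon must be in [0, 0.5), got {epsilon}")
    b, a = _me_rate_coeffs(model, lamb)
    return a * epsilon**2 + b * epsilon


# ---------------------------------------------------------------------------
# independent oracles for the Mendelian-error rate
# ---------------------------------------------------------------------------

_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
# compat tables: can child dosage c arise from parent dosages?
COMPAT2 = np.zeros((3, 3, 3), dtype=bool)
for _f in range(3):
    for _m in range(3):
        for _c in range(3):
            COMPAT2[_f, _m, _c] = any(
                af + am == _c for af in _ALLELES[_f] for am in _ALLELES[_m]
            )
COMPAT1 = np.zeros((3, 3), dtype=bool)
for _p in range(3):
    for _c in range(3):
        COMPAT1[_p, _c] = any(ap + ax == _c for ap in _ALLELES[_p] for ax in (0, 1))


def _family_consistent(dosages: list[int], two_parent: bool) -> bool:
    if two_parent:
        f, m, kids = dosages[0], dosages[1], dosages[2:]
        return all(COMPAT2[f, m, c] for c in kids)
    p, kids = dosages[0], dosages[1:]
    return all(COMPAT1[p, c] for c in kids)


def exact_mendelian_rate(
    model: MendelianRateModel, epsilon: float, lamb: float
) -> float:
    """Exact expected per-locus Mendelian-error rate under the
    single-error-per-locus mechanism, by full enumeration.

    Mechanism: founder alleles iid Bernoulli(lamb); each child inherits one
    allele from each present parent (the absent parent of a one-parent
    family transmits a fresh Bernoulli(lamb) allele); exactly one family
    member errs, with a single-allele flip carrying weight
    epsilon*(1-epsilon) per allele and a double flip weight epsilon^2; the
    family-locus contributes 1 when its dosage vector is inconsistent.
    Serves as the independent oracle for :func:`expected_mendelian_rate`.
    """
    m = model.m
    two_parent = model.family_type is FamilyType.TWO_PARENT
    E = 0.0
    n_founder_alleles = 4 if two_parent else 2
    for founder in itertools.product((0, 1), repeat=n_founder_alleles):
        pf = math.prod(lamb if a else 1 - lamb for a in founder)
        if two_parent:
            fa, mo = founder[:2], founder[2:]
            inherit_space = itertools.product(range(4), repeat=m)
            w_inherit = 0.25**m
        else:
            fa = founder
            inherit_space = itertools.product(range(4), repeat=m)
            w_inherit = None  # weight depends on the free allele
        for picks in inherit_space:
            if two_parent:
                members = [list(fa), list(mo)]
                for pk in picks:
                    members.append([fa[pk >> 1], mo[pk & 1]])
                w = pf * w_inherit
            else:
                members = [list(fa)]
                w = pf
                for pk in picks:
                    src, free = pk >> 1, pk & 1
                    members.append([fa[src], free])
                    w *= 0.5 * (lamb if free else 1 - lamb)
            for j in range(len(members)):
                for pattern, pw in (
                    (0b01, epsilon * (1 - epsilon)),
                    (0b10, epsilon * (1 - epsilon)),
                    (0b11, epsilon * epsilon),
                ):
                    erred = [list(mem) for mem in members]
                    if pattern & 1:
                        erred[j][0] ^= 1
                    if pattern & 2:
                        erred[j][1] ^= 1
                    dos = [a + b for a, b in erred]
                    if not _family_consistent(dos, two_parent):
                        E += w * pw
    return E


def mendelian_rate_mc(
    model: MendelianRateModel,
    epsilon: float,
    lamb: float,
    reps: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of the per-locus
    Mendelian-error rate under the single-error-per-locus mechanism.

    Vectorized over replicates: founders are sampled iid Bernoulli(lamb),
    alleles dropped to children, then for each member in turn an erred copy
    of the family (only that member's alleles flipped, per-allele rate
    epsilon) is checked for dosage inconsistency; the per-replicate count
    sums those indicators over members.
    """
    m = model.m
    two_parent = model.family_type is FamilyType.TWO_PARENT
    draw = lambda size: rng.random(size) < lamb  # noqa: E731

    if two_parent:
        fa = draw((reps, 2)).astype(np.int8)
        mo = draw((reps, 2)).astype(np.int8)
        pick_f = rng.integers(0, 2, size=(reps, m))
        pick_m = rng.integers(0, 2, size=(reps, m))
        kids = np.stack(
            [
                np.stack(
                    [
                        np.take_along_axis(fa, pick_f[:, k : k + 1], axis=1)[:, 0],
                        np.take_along_axis(mo, pick_m[:, k : k + 1], axis=1)[:, 0],
                    ],
                    axis=1,
                )
                for k in range(m)
            ],
            axis=1,
        )  # (reps, m, 2)
        members = np.concatenate([fa[:, None, :], mo[:, None, :], kids], axis=1)
    else:
        pa = draw((reps, 2)).astype(np.int8)
        pick = rng.integers(0, 2, size=(reps, m))
        free = draw((reps, m)).astype(np.int8)
        kids = np.stack(
            [
                np.stack(
                    [
                        np.take_along_axis(pa, pick[:, k : k + 1], axis=1)[:, 0],
                        free[:, k],
                    ],
                    axis=1,
                )
                for k in range(m)
            ],
            axis=1,
        )
        members = np.concatenate([pa[:, None, :], kids], axis=1)

    n_members = members.shape[1]
    truth_dos = members.sum(axis=2)  # (reps, n_members)

    def consistent(dos: np.ndarray) -> np.ndarray:
        if two_parent:
            ok = np.ones(dos.shape[0], dtype=bool)
            for k in range(m):
                ok &= COMPAT2[dos[:, 0], dos[:, 1], dos[:, 2 + k]]
            return ok
        ok = np.ones(dos.shape[0], dtype=bool)
        for k in range(m):
            ok &= COMPAT1[dos[:, 0], dos[:, 1 + k]]
        return ok

    counts = np.zeros(reps)
    for j in range(n_members):
        flips = rng.random((reps, 2)) < epsilon
        erred_j = (members[:, j, :] ^ flips).sum(axis=1)
        dos = truth_dos.copy()
        dos[:, j] = erred_j
        counts += ~consistent(dos)
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / math.sqrt(reps))
    return mean, se


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------


def estimate_lambda(dosages: np.ndarray) -> float:
    """Admixture proportion as the average dosage / 2 over observed cells."""
    d = np.asarray(dosages)
    obs = d[d >= 0]
    if obs.size == 0:
        raise ValueError("no observed dosages to estimate lambda from")
    return float(obs.mean() / 2)


def estimate_epsilon(
    observed_me: list[int] | np.ndarray,
    families: list[MendelianRateModel],
    L: int,
    lamb: float,
) -> float:
    """Estimate the allelic error rate from observed Mendelian-error counts.

    Solves sum_f L * rate_f(eps) = sum_f observed_me_f for eps, where
    rate_f is the family's expected per-locus Mendelian-error polynomial.
    The aggregate is quadratic in eps; returns the root in [0, 0.5) (the
    smaller if two qualify). Raises ValueError when the observed rate
    exceeds what the model can produce on [0, 0.5).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not families:
        raise ValueError("at least one family is required")
    observed_me = np.asarray(observed_me, dtype=float)
    if len(observed_me) != len(families):
        raise ValueError("one observed count per family is required")
    if np.any(observed_me < 0):
        raise ValueError("counts must be >= 0")
    total = float(observed_me.sum())
    if total == 0:
        return 0.0
    B = sum(_me_rate_coeffs(f, lamb)[0] for f in families)
    A = sum(_me_rate_coeffs(f, lamb)[1] for f in families)

    def g(eps: float) -> float:
        return L * (A * eps**2 + B * eps) - total

    # closed-form roots, then a bracketing fallback for robustness
    roots = []
    if A != 0:
        disc = (L * B) ** 2 + 4 * L * A * total
        if disc >= 0:
            for sign in (-1.0, 1.0):
                r = (-L * B + sign * math.sqrt(disc)) / (2 * L * A)
                if 0 <= r < 0.5:
                    roots.append(r)
    elif B != 0:
        r = total / (L * B)
        if 0 <= r < 0.5:
            roots.append(r)
    if roots:
        return min(roots)
    # no closed-form root in range: try bracketing, else report
    lo, hi = g(0.0), g(0.5 - 1e-12)
    if lo * hi < 0:
        return float(brentq(g, 0.0, 0.5 - 1e-12))
    grid = np.linspace(0, 0.5 - 1e-12, 501)
    model_max = max(L * (A * e**2 + B * e) for e in grid)
    raise ValueError(
        f"no epsilon in [0, 0.5) reproduces the observed Mendelian-error total "
        f"{total:.1f} over L={L} loci (observed rate {total / L:.4g} per locus, "
        f"model maximum {model_max / L:.4g})"
    )


def double_crossover_prob(window_M: float, tau: float) -> float:
    """P(two or more crossovers) in a window, crossovers ~ Poisson(window*tau).

    1 - exp(-x) - x*exp(-x) with x = window_M * tau. Small for windows of a
    couple of cM at tau ~ 8, which is why a double crossover returning to
    the prior ancestry within such a window is treated as an error.
    """
    if window_M < 0:
        raise ValueError(f"window must be >= 0, got {window_M}")
    x = window_M * tau
    return float(1 - math.exp(-x) - x * math.exp(-x))
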