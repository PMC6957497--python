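"""Mendelian-consistency checking, error flagging and MAP correction.

The correction model: at a flagged locus t the true dosage configuration
X_t over the pedigree is re-estimated as

    argmax_{X in Ped}  P(Y_t | X) * P(X_right | X) * P(X | X_left)

where Ped is the set of Mendelian-consistent configurations, Y_t the
observed configuration, X_left/X_right the configurations at the nearest
trusted flanking loci (assumed error-free), the inference factor uses the
per-allele flip model and the transition factors the diploid ancestry-
switch model over the flanking genetic distances. All three factors
factorize over individuals. At chromosome boundaries the absent flank is
dropped. The candidate set is restricted to configurations within Hamming
distance ``max_diff`` (default 2) of Y_t; simultaneous errors in three or
more members at one locus are rare enough at realistic error rates that
this loses essentially nothing, and the sweep escalates the radius once
when no candidate exists.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .ancestry_io import AlignedBundle, AncestryMatrix
from .pedigree import FamilyType, NuclearFamily, Pedigree, extract_nuclear_families
from .prob_models import (
    COMPAT1,
    COMPAT2,
    ErrorModelParams,
    MendelianRateModel,
    _me_rate_coeffs,
    diploid_transition,
    estimate_lambda,
    inference_matrix,
)

__all__ = [
    "is_mendelian_consistent",
    "enumerate_ped",
    "enumerate_candidates",
    "flag_loci",
    "correct_locus",
    "correct_all",
    "FlagReason",
    "FlagSet",
    "LocusFlag",
    "CorrectionOutcome",
    "CorrectionReport",
    "EpsilonEstimate",
    "estimate_epsilon_from_matrix",
    "count_mendelian_inconsistent",
    "double_crossover_runs",
]

_PROB_FLOOR = 1e-300  # keeps inadmissible transitions comparable in log space

# ---------------------------------------------------------------------------
# consistency machinery
# ---------------------------------------------------------------------------

# ordered allele pairs indexed 0:(0,0) 1:(0,1) 2:(1,0) 3:(1,1);
# pair bitmask tables for genotype elimination
_DOSAGE_MASK = {0: 0b0001, 1: 0b0110, 2: 0b1000, -1: 0b1111}
_PAIR_ALLELES = [(0, 0), (0, 1), (1, 0), (1, 1)]
# TRANS[mask] = 2-bit set of transmissible alleles
_TRANS = [0] * 16
for _mask in range(16):
    bits = 0
    for _p in range(4):
        if _mask >> _p & 1:
            a, b = _PAIR_ALLELES[_p]
            bits |= 1 << a | 1 << b
    _TRANS[_mask] = bits
# CHILD_ALLOW[tf][tm] = 4-bit mask of child pairs (a1 from father, a2 from mother)
_CHILD_ALLOW = [[0] * 4 for _ in range(4)]
for _tf in range(4):
    for _tm in range(4):
        mask = 0
        for _p, (a1, a2) in enumerate(_PAIR_ALLELES):
            if _tf >> a1 & 1 and _tm >> a2 & 1:
                mask |= 1 << _p
        _CHILD_ALLOW[_tf][_tm] = mask
# PAIR_HAS[need] = 4-bit mask of pairs containing any allele in the 2-bit set
_PAIR_HAS = [0] * 4
for _need in range(4):
    mask = 0
    for _p, (a, b) in enumerate(_PAIR_ALLELES):
        if _need >> a & 1 or _need >> b & 1:
            mask |= 1 << _p
    _PAIR_HAS[_need] = mask


class _Checker:
    """Per-pedigree Mendelian-consistency engine.

    For fully observed configurations the check reduces to independent
    per-(child, parents) table lookups: a parent's allele multiset is fixed
    by its dosage, so the local constraints share no latent variables and
    local consistency of every triple is equivalent to the existence of a
    global ordered-allele assignment. Configurations with missing dosages
    fall back to genotype elimination (constraint propagation over ordered
    allele-pair sets) with a backtracking search to resolve residual
    ambiguity.
    """

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self.triples = ped.constraint_triples()
        # constraints touching each individual index
        self.by_pos: list[list[int]] = [[] for _ in range(ped.n)]
        for k, (c, f, m) in enumerate(self.triples):
            for idx in (c, f, m):
                if idx >= 0:
                    self.by_pos[idx].append(k)

    # -- fully observed path --------------------------------------------
    def constraint_ok(self, config: np.ndarray, k: int) -> bool:
        c, f, m = self.triples[k]
        if f >= 0 and m >= 0:
            return bool(COMPAT2[config[f], config[m], config[c]])
        p = f if f >= 0 else m
        return bool(COMPAT1[config[p], config[c]])

    def constraint_status(self, config: np.ndarray) -> np.ndarray:
        return np.array(
            [self.constraint_ok(config, k) for k in range(len(self.triples))],
            dtype=bool,
        )

    # -- general path (missing dosages) ---------------------------------
    def _propagate(self, masks: list[int]) -> bool:
        triples = self.triples
        changed = True
        while changed:
            changed = False
            for c, f, m in triples:
                tf = _TRANS[masks[f]] if f >= 0 else 0b11
                tm = _TRANS[masks[m]] if m >= 0 else 0b11
                new_c = masks[c] & _CHILD_ALLOW[tf][tm]
                if new_c != masks[c]:
                    masks[c] = new_c
                    changed = True
                if new_c == 0:
                    return False
                need1 = 0
                need2 = 0
                for p, (a1, a2) in enumerate(_PAIR_ALLELES):
                    if new_c >> p & 1:
                        need1 |= 1 << a1
                        need2 |= 1 << a2
                if f >= 0:
                    new_f = masks[f] & _PAIR_HAS[need1]
                    if new_f != masks[f]:
                        masks[f] = new_f
                        changed = True
                    if new_f == 0:
                        return False
                if m >= 0:
                    new_m = masks[m] & _PAIR_HAS[need2]
                    if new_m != masks[m]:
                        masks[m] = new_m
                        changed = True
                    if new_m == 0:
                        return False
        return True

    def _search(self, masks: list[int]) -> bool:
        if not self._propagate(masks):
            return False
        for i, mask in enumerate(masks):
            if bin(mask).count("1") > 1:
                for p in range(4):
                    if mask >> p & 1:
                        trial = list(masks)
                        trial[i] = 1 << p
                        if self._search(trial):
                            return True
                return False
        return True

    def consistent(self, config: np.ndarray) -> bool:
        config = np.asarray(config)
        if (config >= 0).all():
            return all(
                self.constraint_ok(config, k) for k in range(len(self.triples))
            )
        masks = [_DOSAGE_MASK[int(d)] for d in config]
        return self._search(masks)

    def scan(self, dosages: np.ndarray) -> np.ndarray:
        """Per-locus consistency over an (L, n) dosage block."""
        L = dosages.shape[0]
        ok = np.ones(L, dtype=bool)
        full = ~(dosages < 0).any(axis=1)
        D = dosages.clip(0)
        for c, f, m in self.triples:
            if f >= 0 and m >= 0:
                ok[full] &= COMPAT2[D[full, f], D[full, m], D[full, c]]
            else:
                p = f if f >= 0 else m
                ok[full] &= COMPAT1[D[full, p], D[full, c]]
        for t in np.flatnonzero(~full):
            ok[t] = self.consistent(dosages[t])
        return ok


def _get_checker(ped: Pedigree) -> _Checker:
    checker = getattr(ped, "_pedanc_checker", None)
    if checker is None:
        checker = _Checker(ped)
        ped._pedanc_checker = checker
    return checker


def is_mendelian_consistent(config, ped: Pedigree) -> bool:
    """True iff an ordered allele assignment exists in which every child
    receives exactly one allele from each recorded parent and every
    individual's alleles sum to its dosage (missing dosage = -1 leaves the
    individual's alleles unconstrained)."""
    config = np.asarray(config, dtype=np.int8)
    if config.shape != (ped.n,):
        raise ValueError(f"configuration length {config.shape} != pedigree size {ped.n}")
    return _get_checker(ped).consistent(config)


@dataclass(frozen=True)
class PedSet:
    """Materialized set of Mendelian-consistent configurations."""

    configs: np.ndarray  # (k, n) int8, lexicographic order

    def __len__(self) -> int:
        return self.configs.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.configs.tolist()))

    def as_set(self) -> set[tuple[int, ...]]:
        return set(self)

    def __contains__(self, config) -> bool:
        return tuple(config) in self.as_set()


def _all_configs(n: int) -> np.ndarray:
    idx = np.arange(3**n)
    digits = np.empty((3**n, n), dtype=np.int8)
    for j in range(n - 1, -1, -1):
        digits[:, j] = idx % 3
        idx //= 3
    return digits


def enumerate_ped(ped: Pedigree, max_n: int = 12) -> PedSet:
    """All of {0,1,2}^n filtered by Mendelian consistency.

    Full materialization is limited to n <= max_n; larger pedigrees should
    go through :func:`enumerate_candidates`, which only explores the
    neighbourhood of an observed configuration.
    """
    if ped.n > max_n:
        raise ValueError(
            f"pedigree has n={ped.n} > max_n={max_n}; use enumerate_candidates "
            "for a restricted search"
        )
    configs = _all_configs(ped.n)
    checker = _get_checker(ped)
    ok = checker.scan(configs)
    return PedSet(configs=configs[ok])


def enumerate_candidates(
    y, ped: Pedigree, max_diff: int = 2
) -> np.ndarray:
    """Mendelian-consistent configurations within Hamming distance
    ``max_diff`` of ``y`` (changes at observed coordinates, any new value
    in {0,1,2}), ordered by (distance to y, lexicographic).

    Missing coordinates of ``y`` stay missing and unconstrained. Returns an
    (k, n) int8 array, possibly empty.
    """
    y = np.asarray(y, dtype=np.int8)
    if y.shape != (ped.n,):
        raise ValueError(f"configuration length {y.shape} != pedigree size {ped.n}")
    if max_diff < 0:
        raise ValueError("max_diff must be >= 0")
    checker = _get_checker(ped)
    n = ped.n
    observed = [i for i in range(n) if y[i] >= 0]
    has_missing = len(observed) != n

    if not has_missing:
        status = checker.constraint_status(y)
        violated = np.flatnonzero(~status)
        members = [
            frozenset(i for i in checker.triples[k] if i >= 0) for k in violated
        ]
    else:
        violated, members = None, None

    out: list[tuple[int, tuple[int, ...]]] = []

    def try_candidate(positions: tuple[int, ...], values: tuple[int, ...]) -> None:
        cand = y.copy()
        for p, v in zip(positions, values):
            cand[p] = v
        if has_missing:
            ok = checker.consistent(cand)
        else:
            # only constraints touching a changed coordinate can change status
            touched = set()
            for p in positions:
                touched.update(checker.by_pos[p])
            if any(k not in touched for k in violated):
                return
            ok = all(checker.constraint_ok(cand, k) for k in touched)
        if ok:
            out.append((len(positions), tuple(int(v) for v in cand)))

    for k in range(0, max_diff + 1):
        for positions in itertools.combinations(observed, k):
            if not has_missing and len(violated):
                pos_set = set(positions)
                if any(not (mem & pos_set) for mem in members):
                    continue
            alt = [tuple(v for v in (0, 1, 2) if v != y[p]) for p in positions]
            for values in itertools.product(*alt):
                try_candidate(positions, values)

    out.sort()
    if not out:
        return np.empty((0, n), dtype=np.int8)
    return np.array([cfg for _, cfg in out], dtype=np.int8)


# ---------------------------------------------------------------------------
# flagging
# ---------------------------------------------------------------------------


class FlagReason(str, enum.Enum):
    MENDELIAN = "mendelian"
    DOUBLE_CROSSOVER = "double_crossover"
    LOW_QUALITY = "low_quality"


@dataclass(frozen=True)
class LocusFlag:
    locus: int  # global row index in the aligned matrix
    reason: FlagReason
    individuals: tuple[str, ...] = ()
    detail: str = ""


@dataclass
class FlagSet:
    records: list[LocusFlag] = field(default_factory=list)

    def flagged_loci(self) -> list[int]:
        return sorted({r.locus for r in self.records})

    def loci_by_reason(self, reason: FlagReason) -> list[int]:
        return sorted({r.locus for r in self.records if r.reason == reason})

    def counts(self) -> dict[str, int]:
        return {reason.value: len(self.loci_by_reason(reason)) for reason in FlagReason}

    def __len__(self) -> int:
        return len(self.records)


def double_crossover_runs(
    track: np.ndarray, positions_cm: np.ndarray, window_cm: float = 2.0
) -> list[tuple[int, int, float]]:
    """Short return-runs in one individual's dosage track.

    A run is a maximal stretch of constant dosage bounded on both sides by
    dosage changes whose flanking dosages are equal — i.e. a double
    crossover returning to the prior state. To qualify, the run must be the
    *deviating* segment: its genetic span (first-to-last marker) must be
    below ``window_cm`` and no larger than the span of either flanking run,
    otherwise the long stretch between two isolated call errors would
    itself be mistaken for a double crossover. Returns
    (start, stop_exclusive, span_cm) triples in the index space of the
    input arrays. Missing entries are skipped.
    """
    obs = np.flatnonzero(track >= 0)
    if obs.size < 3:
        return []
    vals = track[obs]
    pos = positions_cm[obs]
    # run boundaries over the observed sequence
    change = np.flatnonzero(np.diff(vals) != 0)
    starts = np.concatenate([[0], change + 1])
    stops = np.concatenate([change + 1, [len(vals)]])
    spans = pos[stops - 1] - pos[starts]
    out = []
    for r in range(1, len(starts) - 1):
        left_val = vals[starts[r - 1]]
        right_val = vals[starts[r + 1]]
        if left_val != right_val:
            continue
        span = float(spans[r])
        if span < window_cm and span <= spans[r - 1] and span <= spans[r + 1]:
            out.append((int(obs[starts[r]]), int(obs[stops[r] - 1]) + 1, span))
    return out


def flag_loci(
    bundle: AlignedBundle,
    params: ErrorModelParams | None = None,
    window_cm: float = 2.0,
    quality_threshold: float = 0.90,
) -> FlagSet:
    """Screen the aligned matrix for the three error signatures:
    Mendelian-inconsistent loci, double crossovers shorter than
    ``window_cm``, and calls with quality below ``quality_threshold``."""
    checker = _get_checker(bundle.ped)
    mat = bundle.matrix
    flags = FlagSet()
    for chrom, start, stop in bundle.segments:
        block = mat.dosages[start:stop]
        pos = bundle.gmap.positions_cm(chrom)
        ok = checker.scan(block)
        for t in np.flatnonzero(~ok):
            flags.records.append(
                LocusFlag(locus=start + int(t), reason=FlagReason.MENDELIAN)
            )
        for j, iid in enumerate(mat.individual_ids):
            for r_start, r_stop, span in double_crossover_runs(
                block[:, j], pos, window_cm
            ):
                for t in range(r_start, r_stop):
                    flags.records.append(
                        LocusFlag(
                            locus=start + t,
                            reason=FlagReason.DOUBLE_CROSSOVER,
                            individuals=(iid,),
                            detail=f"span={span:.3f}cM",
                        )
                    )
    if mat.quality is not None:
        low = np.isfinite(mat.quality) & (mat.quality < quality_threshold)
        for t in np.flatnonzero(low.any(axis=1)):
            inds = tuple(
                mat.individual_ids[j] for j in np.flatnonzero(low[t])
            )
            flags.records.append(
                LocusFlag(locus=int(t), reason=FlagReason.LOW_QUALITY, individuals=inds)
            )
    return flags


# ---------------------------------------------------------------------------
# MAP correction
# ---------------------------------------------------------------------------


@dataclass
class CorrectionOutcome:
    config: np.ndarray
    log_prob: float
    runner_up_log_prob: float | None
    n_candidates: int
    hamming: int
    escalated: bool = False
    failed: bool = False


def _score_candidates(
    cands: np.ndarray,
    y: np.ndarray,
    x_left: np.ndarray | None,
    x_right: np.ndarray | None,
    d_left: float,
    d_right: float,
    params: ErrorModelParams,
) -> np.ndarray:
    logPinf = np.log(np.maximum(inference_matrix(params.epsilon), _PROB_FLOOR))
    cmask = cands >= 0
    cidx = cands.clip(0)
    y_obs = (y >= 0) & cmask
    scores = (logPinf[cidx, y.clip(0)[None, :]] * y_obs).sum(axis=1)
    if x_left is not None:
        Tl = np.log(
            np.maximum(diploid_transition(d_left, params.tau, params.lamb), _PROB_FLOOR)
        )
        l_obs = (x_left >= 0) & cmask
        scores += (Tl[x_left.clip(0)[None, :], cidx] * l_obs).sum(axis=1)
    if x_right is not None:
        Tr = np.log(
            np.maximum(diploid_transition(d_right, params.tau, params.lamb), _PROB_FLOOR)
        )
        r_obs = (x_right >= 0) & cmask
        scores += (Tr[cidx, x_right.clip(0)[None, :]] * r_obs).sum(axis=1)
    return scores


def correct_locus(
    y_t,
    x_left,
    x_right,
    d_left: float,
    d_right: float,
    ped: Pedigree,
    params: ErrorModelParams,
    max_diff: int = 2,
) -> CorrectionOutcome:
    """MAP re-estimate of one locus's configuration given trusted flanks.

    At least one flank must be present; an absent flank (chromosome
    boundary) drops the corresponding transition factor. Candidates come
    from :func:`enumerate_candidates`; ties within 1e-12 in log probability
    resolve to the candidate closest to ``y_t`` and then lexicographically
    smallest. If no consistent candidate exists within ``max_diff`` the
    radius is escalated once; if still none, the locus is returned
    unchanged and marked failed.
    """
    y_t = np.asarray(y_t, dtype=np.int8)
    if x_left is None and x_right is None:
        raise ValueError("at least one flanking configuration is required")
    x_left = None if x_left is None else np.asarray(x_left, dtype=np.int8)
    x_right = None if x_right is None else np.asarray(x_right, dtype=np.int8)

    escalated = False
    cands = enumerate_candidates(y_t, ped, max_diff)
    if cands.shape[0] == 0:
        escalated = True
        cands = enumerate_candidates(y_t, ped, max_diff + 1)
    if cands.shape[0] == 0:
        return CorrectionOutcome(
            config=y_t.copy(),
            log_prob=float("-inf"),
            runner_up_log_prob=None,
            n_candidates=0,
            hamming=0,
            escalated=True,
            failed=True,
        )
    scores = _score_candidates(cands, y_t, x_left, x_right, d_left, d_right, params)
    best = scores.max()
    # candidates are ordered by (hamming, lexicographic): first hit wins ties
    winner = int(np.flatnonzero(scores >= best - 1e-12)[0])
    runner_up = None
    if cands.shape[0] > 1:
        others = np.delete(scores, winner)
        runner_up = float(others.max())
    chosen = cands[winner]
    return CorrectionOutcome(
        config=chosen.copy(),
        log_prob=float(scores[winner]),
        runner_up_log_prob=runner_up,
        n_candidates=int(cands.shape[0]),
        hamming=int(((chosen != y_t) & (y_t >= 0)).sum()),
        escalated=escalated,
    )


# ---------------------------------------------------------------------------
# full sweep
# ---------------------------------------------------------------------------


@dataclass
class LocusCorrection:
    locus: int
    original: tuple[int, ...]
    corrected: tuple[int, ...]
    log_prob: float
    runner_up_log_prob: float | None
    reasons: tuple[str, ...]
    escalated: bool


@dataclass
class CorrectionReport:
    """Before/after accounting for one correction run."""

    n_markers: int
    n_individuals: int
    flag_counts: dict[str, int]
    loci_changed: list[int] = field(default_factory=list)
    cells_changed: int = 0
    per_individual_changed: dict[str, int] = field(default_factory=dict)
    mendelian_before: int = 0
    mendelian_after: int = 0
    mendelian_flagged_unresolved: int = 0
    unresolved: list[int] = field(default_factory=list)
    escalated: list[int] = field(default_factory=list)
    corrections: list[LocusCorrection] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_markers": self.n_markers,
            "n_individuals": self.n_individuals,
            "flag_counts": self.flag_counts,
            "n_loci_changed": len(self.loci_changed),
            "cells_changed": self.cells_changed,
            "per_individual_changed": self.per_individual_changed,
            "mendelian_before": self.mendelian_before,
            "mendelian_after": self.mendelian_after,
            "mendelian_flagged_unresolved": self.mendelian_flagged_unresolved,
            "unresolved": self.unresolved,
            "escalated": self.escalated,
        }


def count_mendelian_inconsistent(matrix: AncestryMatrix, ped: Pedigree) -> int:
    """Number of loci whose configuration is Mendelian-inconsistent."""
    checker = _get_checker(ped)
    return int((~checker.scan(matrix.dosages)).sum())


def _blocks(dosages: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of identical configurations, as (start, stop) pairs."""
    L = dosages.shape[0]
    if L == 0:
        return []
    change = np.flatnonzero((dosages[1:] != dosages[:-1]).any(axis=1))
    starts = np.concatenate([[0], change + 1])
    stops = np.concatenate([change + 1, [L]])
    return list(zip(starts.tolist(), stops.tolist()))


def correct_all(
    bundle: AlignedBundle,
    params: ErrorModelParams | None = None,
    *,
    window_cm: float = 2.0,
    quality_threshold: float = 0.90,
    max_diff: int = 2,
    mode: str = "marker",
    sweeps: int = 1,
    flags: FlagSet | None = None,
) -> tuple[AncestryMatrix, CorrectionReport]:
    """Left-to-right correction sweep over all flagged loci (or blocks).

    ``params`` may omit epsilon entirely (pass None) in which case lambda
    is taken as the sample-mean ancestry proportion and epsilon is
    estimated from Mendelian errors in the pedigree's nuclear families.
    Corrected loci are trusted as left-flank context for subsequent loci;
    the right flank is the nearest locus carrying no flag. In ``block``
    mode maximal runs of identical configurations are corrected as single
    units, with the flanking blocks as neighbours.
    """
    if mode not in ("marker", "block"):
        raise ValueError(f"mode must be 'marker' or 'block', got {mode!r}")
    if params is None:
        est = estimate_epsilon_from_matrix(bundle.matrix, bundle.ped)
        params = ErrorModelParams(epsilon=est.epsilon, lamb=est.lamb)
    if flags is None:
        flags = flag_loci(
            bundle, params, window_cm=window_cm, quality_threshold=quality_threshold
        )

    mat = bundle.matrix
    corrected = mat.copy()
    checker = _get_checker(bundle.ped)
    report = CorrectionReport(
        n_markers=mat.n_markers,
        n_individuals=mat.n_individuals,
        flag_counts=flags.counts(),
        mendelian_before=count_mendelian_inconsistent(mat, bundle.ped),
        per_individual_changed={iid: 0 for iid in mat.individual_ids},
    )
    flagged = set(flags.flagged_loci())
    reasons_at = {}
    for rec in flags.records:
        reasons_at.setdefault(rec.locus, set()).add(rec.reason.value)

    positions = bundle.positions_cm()

    for _ in range(sweeps):
        for chrom, start, stop in bundle.segments:
            seg_flagged = [t for t in range(start, stop) if t in flagged]
            if not seg_flagged:
                continue
            if mode == "marker":
                _sweep_markers(
                    corrected,
                    seg_flagged,
                    start,
                    stop,
                    positions,
                    flagged,
                    bundle.ped,
                    params,
                    max_diff,
                    report,
                    reasons_at,
                )
            else:
                _sweep_blocks(
                    corrected,
                    start,
                    stop,
                    positions,
                    flagged,
                    bundle.ped,
                    params,
                    max_diff,
                    report,
                    reasons_at,
                )

    # accounting
    diff = (corrected.dosages != mat.dosages) & (mat.dosages >= 0)
    report.cells_changed = int(diff.sum())
    report.loci_changed = np.flatnonzero(diff.any(axis=1)).tolist()
    for j, iid in enumerate(mat.individual_ids):
        report.per_individual_changed[iid] = int(diff[:, j].sum())
    report.mendelian_after = count_mendelian_inconsistent(corrected, bundle.ped)
    me_flagged = [
        t for t in flagged if "mendelian" in reasons_at.get(t, set())
    ]
    if me_flagged:
        still_bad = ~checker.scan(corrected.dosages[sorted(me_flagged)])
        report.mendelian_flagged_unresolved = int(still_bad.sum())
    return corrected, report


def _trusted_left(t: int, start: int, flagged: set[int], resolved: set[int]) -> int | None:
    for u in range(t - 1, start - 1, -1):
        if u not in flagged or u in resolved:
            return u
    return None


def _unflagged_right(t: int, stop: int, flagged: set[int]) -> int | None:
    for u in range(t + 1, stop):
        if u not in flagged:
            return u
    return None


def _sweep_markers(
    corrected, seg_flagged, start, stop, positions, flagged, ped, params,
    max_diff, report, reasons_at,
):
    resolved: set[int] = set()
    D = corrected.dosages
    for t in seg_flagged:
        left = _trusted_left(t, start, flagged, resolved)
        right = _unflagged_right(t, stop, flagged)
        if left is None and right is None:
            report.unresolved.append(t)
            continue
        d_left = (positions[t] - positions[left]) / 100.0 if left is not None else 0.0
        d_right = (positions[right] - positions[t]) / 100.0 if right is not None else 0.0
        outcome = correct_locus(
            D[t],
            D[left] if left is not None else None,
            D[right] if right is not None else None,
            d_left,
            d_right,
            ped,
            params,
            max_diff,
        )
        _record(outcome, t, D, resolved, report, reasons_at)


def _sweep_blocks(
    corrected, start, stop, positions, flagged, ped, params, max_diff, report,
    reasons_at,
):
    D = corrected.dosages
    blocks = [(start + a, start + b) for a, b in _blocks(D[start:stop])]
    is_flagged = [any(t in flagged for t in range(a, b)) for a, b in blocks]
    resolved_blocks: set[int] = set()
    for k, (a, b) in enumerate(blocks):
        if not is_flagged[k]:
            continue
        left = next(
            (
                j
                for j in range(k - 1, -1, -1)
                if not is_flagged[j] or j in resolved_blocks
            ),
            None,
        )
        right = next((j for j in range(k + 1, len(blocks)) if not is_flagged[j]), None)
        if left is None and right is None:
            report.unresolved.extend(range(a, b))
            continue
        d_left = (
            (positions[a] - positions[blocks[left][1] - 1]) / 100.0
            if left is not None
            else 0.0
        )
        d_right = (
            (positions[blocks[right][0]] - positions[b - 1]) / 100.0
            if right is not None
            else 0.0
        )
        outcome = correct_locus(
            D[a],
            D[blocks[left][1] - 1] if left is not None else None,
            D[blocks[right][0]] if right is not None else None,
            d_left,
            d_right,
            ped,
            params,
            max_diff,
        )
        if outcome.failed:
            report.unresolved.extend(range(a, b))
            if outcome.escalated:
                report.escalated.extend(range(a, b))
            continue
        reasons = set()
        for t in range(a, b):
            reasons |= reasons_at.get(t, set())
        for t in range(a, b):
            if not np.array_equal(D[t], outcome.config):
                report.corrections.append(
                    LocusCorrection(
                        locus=t,
                        original=tuple(int(v) for v in D[t]),
                        corrected=tuple(int(v) for v in outcome.config),
                        log_prob=outcome.log_prob,
                        runner_up_log_prob=outcome.runner_up_log_prob,
                        reasons=tuple(sorted(reasons)),
                        escalated=outcome.escalated,
                    )
                )
            D[t] = outcome.config
        resolved_blocks.add(k)
        if outcome.escalated:
            report.escalated.extend(range(a, b))


def _record(outcome, t, D, resolved, report, reasons_at):
    if outcome.failed:
        report.unresolved.append(t)
        if outcome.escalated:
            report.escalated.append(t)
        return
    if outcome.escalated:
        report.escalated.append(t)
    if not np.array_equal(D[t], outcome.config):
        report.corrections.append(
            LocusCorrection(
                locus=t,
                original=tuple(int(v) for v in D[t]),
                corrected=tuple(int(v) for v in outcome.config),
                log_prob=outcome.log_prob,
                runner_up_log_prob=outcome.runner_up_log_prob,
                reasons=tuple(sorted(reasons_at.get(t, set()))),
                escalated=outcome.escalated,
            )
        )
        D[t] = outcome.config
    resolved.add(t)


# ---------------------------------------------------------------------------
# epsilon estimation from a matrix + pedigree
# ---------------------------------------------------------------------------


@dataclass
class EpsilonEstimate:
    epsilon: float
    lamb: float
    families: list[NuclearFamily]
    me_counts: list[int]
    loci_used: list[int]


def count_family_mendelian_errors(
    matrix: AncestryMatrix, family: NuclearFamily
) -> tuple[int, int]:
    """(Mendelian-inconsistent locus count, loci evaluated) for one nuclear
    family; loci with any missing member call are excluded."""
    cols = [matrix.individual_ids.index(i) for i in family.member_ids]
    D = matrix.dosages[:, cols]
    full = ~(D < 0).any(axis=1)
    D = D[full].clip(0)
    n_par = len(family.parent_ids)
    ok = np.ones(D.shape[0], dtype=bool)
    for k in range(family.m):
        if n_par == 2:
            ok &= COMPAT2[D[:, 0], D[:, 1], D[:, n_par + k]]
        else:
            ok &= COMPAT1[D[:, 0], D[:, n_par + k]]
    return int((~ok).sum()), int(full.sum())


def estimate_epsilon_from_matrix(
    matrix: AncestryMatrix,
    ped: Pedigree,
    lamb: float | None = None,
) -> EpsilonEstimate:
    """Estimate the allelic error rate from Mendelian errors in the
    pedigree's non-overlapping nuclear families.

    Divides the pedigree, counts Mendelian-inconsistent family-loci, and
    solves the aggregate quadratic (summing each family's expected-rate
    polynomial weighted by its evaluated locus count) for epsilon in
    [0, 0.5). lambda defaults to the sample-mean ancestry proportion.
    """
    if lamb is None:
        # clamp away from the open-interval bounds for degenerate samples
        lamb = min(max(estimate_lambda(matrix.dosages), 1e-6), 1 - 1e-6)
    families, _ = extract_nuclear_families(ped)
    families = [f for f in families if all(i in matrix.individual_ids for i in f.member_ids)]
    if not families:
        raise ValueError("no nuclear families available for estimation")
    counts, loci = [], []
    B = A = 0.0
    for fam in families:
        c, L_f = count_family_mendelian_errors(matrix, fam)
        counts.append(c)
        loci.append(L_f)
        model = MendelianRateModel(family_type=fam.type, m=fam.m)
        b, a = _me_rate_coeffs(model, lamb)
        B += L_f * b
        A += L_f * a
    total = float(sum(counts))
    if total == 0:
        eps = 0.0
    else:
        roots = []
        if A != 0:
            disc = B**2 + 4 * A * total
            if disc >= 0:
                for sign in (-1.0, 1.0):
                    r = (-B + sign * math.sqrt(disc)) / (2 * A)
                    if 0 <= r < 0.5:
                        roots.append(r)
        elif B != 0:
            r = total / B
            if 0 <= r < 0.5:
                roots.append(r)
        if not roots:
            raise ValueError(
                f"no epsilon in [0, 0.5) reproduces {total:.0f} Mendelian-error "
                f"loci over {sum(loci)} family-loci"
            )
        eps = min(roots)
    return EpsilonEstimate(
        epsilon=eps, lamb=lamb, families=families, me_counts=counts, loci_used=loci
    )
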