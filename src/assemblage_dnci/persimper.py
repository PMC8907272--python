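"""PER-SIMPER null models and the dispersal-niche continuum index (DNCI).

SIMPER decomposes the overall average dissimilarity (OAD) between two
clusters of levels into per-taxon percent contributions. The rank-ordered
(descending) percent vector — the SIMPER *profile* — is then compared with
profiles obtained after randomising the incidence submatrix under three
constraint schemes:

``dispersal``
    column (taxon) totals fixed, presences shuffled across levels: each
    taxon keeps its overall occurrence frequency (a dispersal-ability
    signature) while level composition is randomised;
``niche``
    row (level) totals fixed, presences shuffled across taxa: each level
    keeps its richness (a local niche-capacity signature) while taxon
    identity is randomised;
``both``
    both margins fixed via the curveball trial-swap algorithm (diagnostic
    only; it does not enter the DNCI).

The fit of a null is the E statistic, log10 of the summed squared rank-wise
profile differences — the closer a null reproduces the empirical profile,
the lower its E. The DNCI contrasts the two single-constraint nulls:
DNCI_m = (E_dispersal,m - E_niche,m) / s with s the pooled standard
deviation of all E values; significantly negative means dispersal-assembled,
significantly positive niche-assembled, and an interval overlapping zero
means both processes contribute. Uneven cluster sizes bias the index toward
zero, so the larger cluster is repeatedly subsampled to the smaller size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .exceptions import (
    AnalysisNotPossibleError,
    ConfigurationError,
    UndefinedDNCIError,
    ValidationError,
)
from .occurrence import IncidenceMatrix

SCHEMES = ("dispersal", "niche", "both")

#: Floor inside the log when a permuted profile matches exactly.
E_EPSILON = 1e-12


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------


@dataclass
class SimperProfile:
    """Per-taxon percent contributions to the overall average dissimilarity."""

    oad: float
    contributions: dict[str, float]
    profile: np.ndarray
    cases: dict[str, str] = field(default_factory=dict)

    def table(self) -> list[tuple[str, float, float]]:
        """(taxon, percent, cumulative percent) rows, descending."""
        rows = sorted(self.contributions.items(), key=lambda kv: (-kv[1], kv[0]))
        out, cum = [], 0.0
        for taxon, pct in rows:
            cum += pct
            out.append((taxon, pct, cum))
        return out


def _profile_percents(X: np.ndarray, n1: int) -> tuple[float, np.ndarray]:
    """OAD and per-taxon mean contributions for a stacked submatrix.

    ``X`` holds group-1 levels in rows ``:n1`` and group-2 levels after.
    For a between-group level pair (j, k) the binary Bray-Curtis share of
    taxon i is |x_ij - x_ik| / sum_i (x_ij + x_ik); contributions average
    over all valid pairs (pairs where both levels are empty are skipped).
    """
    A = X[:n1].astype(float)
    B = X[n1:].astype(float)
    rsA = A.sum(axis=1)
    rsB = B.sum(axis=1)
    denom = rsA[:, None] + rsB[None, :]
    valid = denom > 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros(X.shape[1])
    w = np.where(valid, 1.0, 0.0) / np.where(valid, denom, 1.0)
    # sum_jk w_jk |A_ji - B_ki| with |diff| = A + B - 2AB for binary data
    term = A.T @ w.sum(axis=1) + B.T @ w.sum(axis=0) - 2.0 * ((w @ B) * A).sum(axis=0)
    contrib = term / n_valid
    return float(contrib.sum()), contrib


def _distribution_case(occ1: float, occ2: float) -> str:
    """Tag a taxon by how it is distributed across the two clusters:
    widespread vs rare, and even vs concentrated in one cluster."""
    top = max(occ1, occ2)
    widespread = "widespread" if top >= 0.5 else "rare"
    if top == 0:
        return f"{widespread}-even"
    even = "even" if min(occ1, occ2) / top >= 0.5 else "in-one"
    return f"{widespread}-{even}"


def _pair_submatrix(
    m: IncidenceMatrix, group1: Iterable[str], group2: Iterable[str]
) -> tuple[np.ndarray, int, list[str]]:
    g1 = [str(x) for x in group1]
    g2 = [str(x) for x in group2]
    if set(g1) & set(g2):
        raise ValidationError("groups must be disjoint")
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each group needs at least 2 levels")
    sub = m.subset(levels=g1 + g2)
    if (sub.values.sum(axis=1) == 0).any():
        raise ValidationError("a level with zero taxa inside a group")
    # canonical (sorted) taxon order so results do not depend on column order
    keep = sorted(
        tx for tx, s in zip(sub.taxon_ids, sub.values.sum(axis=0)) if s > 0
    )
    sub = sub.subset(taxa=keep)
    return sub.values.astype(np.int8), len(g1), list(sub.taxon_ids)


def simper(
    m: IncidenceMatrix, group1: Iterable[str], group2: Iterable[str]
) -> SimperProfile:
    """SIMPER decomposition of the OAD between two groups of levels.

    Taxa absent from both groups are dropped first. If the groups are
    compositionally identical (OAD = 0) an empty profile is returned.
    """
    X, n1, taxa = _pair_submatrix(m, group1, group2)
    oad, contrib = _profile_percents(X, n1)
    total = contrib.sum()
    if total <= 0.0:
        return SimperProfile(oad=0.0, contributions={}, profile=np.array([]))
    percents = 100.0 * contrib / total
    occ1 = X[:n1].mean(axis=0)
    occ2 = X[n1:].mean(axis=0)
    cases = {
        tx: _distribution_case(float(o1), float(o2))
        for tx, o1, o2 in zip(taxa, occ1, occ2)
    }
    return SimperProfile(
        oad=oad,
        contributions={tx: float(p) for tx, p in zip(taxa, percents)},
        profile=np.sort(percents)[::-1],
        cases=cases,
    )


# ---------------------------------------------------------------------------
# Permutation null models
# ---------------------------------------------------------------------------


def _permute_rowfix(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Reassign each row's presences to uniformly random columns (row sums
    conserved exactly)."""
    n, t = X.shape
    order = np.argsort(rng.random((n, t)), axis=1)
    mask = (np.arange(t)[None, :] < X.sum(axis=1)[:, None]).astype(X.dtype)
    out = np.zeros_like(X)
    np.put_along_axis(out, order, mask, axis=1)
    return out


def _permute_colfix(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Reassign each column's presences to uniformly random rows (column
    sums conserved exactly)."""
    return _permute_rowfix(np.ascontiguousarray(X.T), rng).T


def default_curveball_trades(shape: tuple[int, int]) -> int:
    return 5 * max(shape)


def _curveball_trades(
    rows: list[set[int]], n_trades: int, rng: np.random.Generator
) -> None:
    """In-place curveball trial swaps preserving both margins."""
    n = len(rows)
    for _ in range(n_trades):
        i, j = rng.choice(n, size=2, replace=False)
        only_i = list(rows[i] - rows[j])
        only_j = list(rows[j] - rows[i])
        pool = only_i + only_j
        if not only_i or not only_j:
            continue
        rng.shuffle(pool)
        take_i = set(pool[: len(only_i)])
        shared = rows[i] & rows[j]
        rows[i] = shared | take_i
        rows[j] = shared | (set(pool) - take_i)


def _permute_both(X: np.ndarray, rng: np.random.Generator, n_trades: int | None = None) -> np.ndarray:
    rows = [set(np.flatnonzero(r)) for r in X]
    _curveball_trades(rows, n_trades or default_curveball_trades(X.shape), rng)
    out = np.zeros_like(X)
    for i, cols in enumerate(rows):
        out[i, list(cols)] = 1
    return out


def permute(
    m: IncidenceMatrix,
    scheme: str,
    rng: np.random.Generator | int | None = None,
    n_trades: int | None = None,
) -> IncidenceMatrix:
    """One randomised copy of the matrix under a constraint scheme.

    ``niche`` conserves row (level) sums, ``dispersal`` conserves column
    (taxon) sums, ``both`` conserves both margins via curveball trial swaps
    (default 5 * max(n_levels, n_taxa) trades).
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    rng = np.random.default_rng(rng)
    X = m.values
    if scheme == "niche":
        out = _permute_rowfix(X, rng)
    elif scheme == "dispersal":
        out = _permute_colfix(X, rng)
    else:
        out = _permute_both(X, rng, n_trades)
    return IncidenceMatrix(out, list(m.level_ids), list(m.taxon_ids), dict(m.metadata))


# ---------------------------------------------------------------------------
# E statistic
# ---------------------------------------------------------------------------


def _e_from_sorted(emp_sorted: np.ndarray, perm_percents: np.ndarray) -> float:
    perm_sorted = np.sort(perm_percents)[::-1]
    ss = float(((emp_sorted - perm_sorted) ** 2).sum())
    return float(np.log10(ss)) if ss > 0.0 else float(np.log10(E_EPSILON))


def e_statistic(
    empirical: SimperProfile | np.ndarray,
    permuted: SimperProfile | np.ndarray,
    length: int | None = None,
) -> float:
    """E = log10( sum_r (P_emp(r) - P_perm(r))^2 ) over profile ranks.

    Profiles are padded with zeros to a common length (the full taxa set of
    the two clusters); identical profiles hit the 1e-12 floor, E = -12.
    """
    p_emp = empirical.profile if isinstance(empirical, SimperProfile) else np.asarray(empirical, float)
    p_per = permuted.profile if isinstance(permuted, SimperProfile) else np.asarray(permuted, float)
    if length is None:
        length = max(len(p_emp), len(p_per))
    if len(p_emp) > length or len(p_per) > length:
        raise ValidationError("profile longer than requested padding length")
    a = np.zeros(length)
    b = np.zeros(length)
    a[: len(p_emp)] = np.sort(p_emp)[::-1]
    b[: len(p_per)] = np.sort(p_per)[::-1]
    ss = float(((a - b) ** 2).sum())
    return float(np.log10(ss)) if ss > 0.0 else float(np.log10(E_EPSILON))


@dataclass
class EDistribution:
    """Null E statistics for one permutation scheme."""

    scheme: str
    e_values: np.ndarray
    n_perm: int

    def __post_init__(self) -> None:
        self.e_values = np.asarray(self.e_values, dtype=float)
        if len(self.e_values) != self.n_perm:
            raise ValidationError("e_values length must equal n_perm")
        if not np.isfinite(self.e_values).all():
            raise ValidationError("E values must be finite")


def _empirical_percents(X: np.ndarray, n1: int) -> np.ndarray:
    oad, contrib = _profile_percents(X, n1)
    total = contrib.sum()
    if oad <= 0.0 or total <= 0.0:
        raise UndefinedDNCIError("empirical overall average dissimilarity is zero")
    return 100.0 * contrib / total


def _null_e_values(
    X: np.ndarray,
    n1: int,
    scheme: str,
    n_perm: int,
    rng: np.random.Generator,
    emp_sorted: np.ndarray | None = None,
) -> np.ndarray:
    """E for ``n_perm`` permutations of the stacked submatrix ``X``."""
    if emp_sorted is None:
        emp_sorted = np.sort(_empirical_percents(X, n1))[::-1]
    out = np.empty(n_perm)
    if scheme == "both":
        rows = [set(np.flatnonzero(r)) for r in X]
        n_trades = default_curveball_trades(X.shape)
        Xp = np.zeros_like(X)
    for i in range(n_perm):
        if scheme == "niche":
            Xp = _permute_rowfix(X, rng)
        elif scheme == "dispersal":
            Xp = _permute_colfix(X, rng)
        else:  # chained curveball draws
            _curveball_trades(rows, n_trades, rng)
            Xp[:] = 0
            for r, cols in enumerate(rows):
                Xp[r, list(cols)] = 1
        _, contrib = _profile_percents(Xp, n1)
        total = contrib.sum()
        if total <= 0.0:
            out[i] = float(np.log10((emp_sorted**2).sum()))
            continue
        out[i] = _e_from_sorted(emp_sorted, 100.0 * contrib / total)
    return out


def e_distribution(
    m: IncidenceMatrix,
    group1: Iterable[str],
    group2: Iterable[str],
    scheme: str,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> EDistribution:
    """Distribution of E under one permutation scheme, restricted to the
    two clusters' submatrix."""
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(rng)
    X, n1, _ = _pair_submatrix(m, group1, group2)
    return EDistribution(scheme, _null_e_values(X, n1, scheme, n_perm, rng), n_perm)


def persimper_report(
    m: IncidenceMatrix,
    group1: Iterable[str],
    group2: Iterable[str],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> dict[str, EDistribution]:
    """Three-way PER-SIMPER comparison (dispersal / niche / both nulls)."""
    rng = np.random.default_rng(rng)
    X, n1, _ = _pair_submatrix(m, group1, group2)
    return {
        scheme: EDistribution(scheme, _null_e_values(X, n1, scheme, n_perm, rng), n_perm)
        for scheme in SCHEMES
    }


# ---------------------------------------------------------------------------
# DNCI
# ---------------------------------------------------------------------------


@dataclass
class DNCIResult:
    """Mean DNCI with a +/- ci_multiplier * SD interval and classification."""

    dnci: float
    ci_low: float
    ci_high: float
    per_subsample: np.ndarray
    classification: str
    n_perm: int
    n_subsamples: int
    cluster_sizes: tuple[int, ...]
    seed: int | None = None
    dnci_values: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    def to_dict(self) -> dict:
        return {
            "dnci": round(self.dnci, 6),
            "ci_low": round(self.ci_low, 6),
            "ci_high": round(self.ci_high, 6),
            "classification": self.classification,
            "n_perm": self.n_perm,
            "n_subsamples": self.n_subsamples,
            "cluster_sizes": list(self.cluster_sizes),
            "seed": self.seed,
        }


def classify(ci_low: float, ci_high: float) -> str:
    """dispersal if the interval is entirely negative, niche if entirely
    positive, otherwise both."""
    if ci_high < 0.0:
        return "dispersal"
    if ci_low > 0.0:
        return "niche"
    return "both"


def _dnci_values_once(
    X: np.ndarray, n1: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-permutation DNCI_m = (E_dispersal,m - E_niche,m) / pooled SD."""
    emp_sorted = np.sort(_empirical_percents(X, n1))[::-1]
    e_d = _null_e_values(X, n1, "dispersal", n_perm, rng, emp_sorted)
    e_n = _null_e_values(X, n1, "niche", n_perm, rng, emp_sorted)
    s = float(np.std(np.concatenate([e_d, e_n]), ddof=1))
    if s == 0.0:
        raise UndefinedDNCIError("degenerate null E distributions (zero spread)")
    return (e_d - e_n) / s


def _drop_empty_cols(X: np.ndarray) -> np.ndarray:
    return X[:, X.sum(axis=0) > 0]


def dnci_pair(
    m: IncidenceMatrix,
    group1: Iterable[str],
    group2: Iterable[str],
    n_perm: int = 1000,
    n_subsamples: int = 100,
    rng: np.random.Generator | int | None = None,
    subsample: bool = True,
    ci_multiplier: float = 2.0,
    imbalance_tolerance: float = 0.0,
) -> DNCIResult:
    """DNCI between two clusters of levels.

    For balanced clusters the index is the mean of the per-permutation
    DNCI_m with CI = mean +/- ci_multiplier * SD(DNCI_m). When cluster sizes
    differ by more than ``imbalance_tolerance`` (relative to the smaller
    cluster) and ``subsample`` is enabled, the computation is repeated on
    ``n_subsamples`` random reductions of the larger cluster to the smaller
    size; the point estimate is the mean of per-subsample means and the CI
    is built from the pooled per-subsample DNCI_m values.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    g1 = [str(x) for x in group1]
    g2 = [str(x) for x in group2]
    X, n1, _ = _pair_submatrix(m, g1, g2)
    n2 = X.shape[0] - n1
    sizes_differ = min(n1, n2) == 0 or abs(n1 - n2) / min(n1, n2) > imbalance_tolerance
    if n1 == n2 or not sizes_differ or not subsample:
        values = _dnci_values_once(_drop_empty_cols(X), n1, n_perm, rng)
        dnci = float(values.mean())
        half = ci_multiplier * float(values.std(ddof=1))
        per_subsample = np.array([dnci])
        cluster_sizes: tuple[int, ...] = (n1, n2)
        n_sub_used = 0
    else:
        small = min(n1, n2)
        means = np.empty(n_subsamples)
        pooled = np.empty(n_subsamples * n_perm)
        A, B = X[:n1], X[n1:]
        for s_ix in range(n_subsamples):
            a = A[np.sort(rng.choice(n1, size=small, replace=False))] if n1 > small else A
            b = B[np.sort(rng.choice(n2, size=small, replace=False))] if n2 > small else B
            sub = _drop_empty_cols(np.vstack([a, b]))
            vals = _dnci_values_once(sub, small, n_perm, rng)
            means[s_ix] = vals.mean()
            pooled[s_ix * n_perm : (s_ix + 1) * n_perm] = vals
        values = pooled
        dnci = float(means.mean())
        half = ci_multiplier * float(pooled.std(ddof=1))
        per_subsample = means
        cluster_sizes = (small, small)
        n_sub_used = n_subsamples
    ci_low, ci_high = dnci - half, dnci + half
    return DNCIResult(
        dnci=dnci,
        ci_low=ci_low,
        ci_high=ci_high,
        per_subsample=per_subsample,
        classification=classify(ci_low, ci_high),
        n_perm=n_perm,
        n_subsamples=n_sub_used,
        cluster_sizes=cluster_sizes,
        seed=seed,
        dnci_values=values,
    )


@dataclass
class PairwiseDNCI:
    """DNCI (or a typed failure) for one unordered cluster pair."""

    cluster_a: int
    cluster_b: int
    result: DNCIResult | None
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "clusters": [self.cluster_a, self.cluster_b],
            "result": None if self.result is None else self.result.to_dict(),
            "error": self.error,
        }


def dnci_multigroup(
    m: IncidenceMatrix,
    assignment: "dict[str, int] | object",
    n_perm: int = 1000,
    n_subsamples: int = 100,
    rng: np.random.Generator | int | None = None,
    subsample: bool = True,
    ci_multiplier: float = 2.0,
    imbalance_tolerance: float = 0.0,
) -> tuple[DNCIResult, list[PairwiseDNCI]]:
    """DNCI over every unordered pair of retained clusters.

    The overall index is the unweighted mean of the pairwise means; its CI
    pools the per-permutation indices of all pairs. Per-pair undefined-DNCI
    failures are recorded, not raised; with fewer than two clusters (or no
    computable pair) an :class:`AnalysisNotPossibleError` is raised.
    """
    if hasattr(assignment, "assignment"):
        assignment = assignment.assignment  # accept a ClusteringResult
    groups: dict[int, list[str]] = {}
    for lv, c in assignment.items():
        groups.setdefault(int(c), []).append(lv)
    cluster_ids = sorted(groups)
    if len(cluster_ids) < 2:
        raise AnalysisNotPossibleError("fewer than 2 clusters after singleton removal")
    rng = np.random.default_rng(rng)
    pairs = [(a, b) for i, a in enumerate(cluster_ids) for b in cluster_ids[i + 1 :]]
    child_rngs = rng.spawn(len(pairs))
    pairwise: list[PairwiseDNCI] = []
    for (a, b), child in zip(pairs, child_rngs):
        try:
            res = dnci_pair(
                m,
                groups[a],
                groups[b],
                n_perm=n_perm,
                n_subsamples=n_subsamples,
                rng=child,
                subsample=subsample,
                ci_multiplier=ci_multiplier,
                imbalance_tolerance=imbalance_tolerance,
            )
            pairwise.append(PairwiseDNCI(a, b, res))
        except (UndefinedDNCIError, ValidationError) as exc:
            pairwise.append(PairwiseDNCI(a, b, None, error=str(exc)))
    ok = [p.result for p in pairwise if p.result is not None]
    if not ok:
        raise AnalysisNotPossibleError("no cluster pair yielded a defined DNCI")
    if len(ok) == 1:
        overall = ok[0]
    else:
        dnci = float(np.mean([r.dnci for r in ok]))
        pooled = np.concatenate([r.dnci_values for r in ok])
        half = ci_multiplier * float(pooled.std(ddof=1))
        overall = DNCIResult(
            dnci=dnci,
            ci_low=dnci - half,
            ci_high=dnci + half,
            per_subsample=np.concatenate([r.per_subsample for r in ok]),
            classification=classify(dnci - half, dnci + half),
            n_perm=n_perm,
            n_subsamples=max(r.n_subsamples for r in ok),
            cluster_sizes=tuple(len(groups[c]) for c in cluster_ids),
            dnci_values=pooled,
        )
    return overall, pairwise
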