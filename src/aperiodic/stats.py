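"""Inference on aperiodic-exponent tables.

Two inferential tools operate on the long-format exponent tables produced
by the spectral-parameterization stage:

* a fully within-subject factorial ANOVA for 2-level factors (time x drug x
  prime x flanker).  Every effect in a 2^k within design is a single-df
  contrast, so each F statistic is the squared paired t statistic on the
  per-subject contrast scores, with df (1, n-1).  With all factors at two
  levels the Greenhouse-Geisser sphericity correction is the identity
  (sphericity is trivially satisfied for 1-df effects), so only Bonferroni
  correction is applied where follow-up ANOVAs multiply the family.

* an electrode-space cluster-based permutation test: per-electrode paired
  statistics (F or t) are thresholded at a sample-level alpha, adjacent
  suprathreshold electrodes are grouped into connected clusters (separately
  by sign for t), the cluster mass is the sum of member statistics, and the
  Monte-Carlo null of the maximum |mass| is built from within-subject
  sign flips of the paired differences (exact exchangeability under the
  paired null, with max-statistic family-wise error control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay

from .exceptions import DataError, InputError

__all__ = [
    "MontageAdjacency",
    "equidistant_montage",
    "EffectResult",
    "AnovaResults",
    "WithinSubjectAnova",
    "rm_anova",
    "follow_up_anovas",
    "ClusterResult",
    "ClusterTestResult",
    "cluster_permutation_test",
    "electrodewise_condition_tests",
]


# ---------------------------------------------------------------------------
# montage / adjacency
# ---------------------------------------------------------------------------

@dataclass
class MontageAdjacency:
    """Symmetric, irreflexive electrode neighbourhood graph."""

    names: list[str]
    matrix: np.ndarray  # boolean (n, n)
    positions: np.ndarray | None = None  # (n, 2) projected layout

    def __post_init__(self):
        m = np.asarray(self.matrix, bool)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.names):
            raise InputError("adjacency matrix shape/name mismatch")
        if not np.array_equal(m, m.T):
            raise InputError("adjacency must be symmetric")
        if m.diagonal().any():
            raise InputError("adjacency must have no self-loops")
        self.matrix = m
        n_comp, labels = connected_components(csr_matrix(m), directed=False)
        self._components = labels
        if n_comp > 1:
            comps = [
                [self.names[i] for i in np.flatnonzero(labels == c)]
                for c in range(n_comp)
            ]
            warnings.warn(f"adjacency is disconnected: components {comps}")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def is_connected(self) -> bool:
        return len(np.unique(self._components)) == 1

    @property
    def neighbors(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.matrix[i]) for i in range(self.n)]

    @classmethod
    def from_edges(cls, names: list[str], edges) -> "MontageAdjacency":
        idx = {n: i for i, n in enumerate(names)}
        m = np.zeros((len(names), len(names)), bool)
        for a, b in edges:
            i, j = idx[a], idx[b]
            if i == j:
                continue
            m[i, j] = m[j, i] = True
        return cls(names, m)


def _disk_layout(n: int) -> np.ndarray:
    """Near-equidistant 2-D scalp projection: sunflower (Fermat) layout."""
    k = np.arange(1, n + 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt((k - 0.5) / n)
    th = k * golden
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def equidistant_montage(n: int = 60, prune_factor: float = 1.5) -> MontageAdjacency:
    """Default adjacency for an equidistant n-electrode cap.

    Electrodes are laid out near-uniformly on a unit-disk scalp projection,
    triangulated (Delaunay), and edges longer than ``prune_factor`` times the
    median edge are removed.  The result is deterministic, symmetric and
    connected for the default n=60.
    """
    pos = _disk_layout(n)
    if n <= 3:  # triangulation degenerate; tiny caps are fully connected
        m = ~np.eye(n, dtype=bool)
        return MontageAdjacency([f"E{i + 1:02d}" for i in range(n)], m, pos)
    tri = Delaunay(pos)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            edges.add((i, j))
    lengths = {e: np.linalg.norm(pos[e[0]] - pos[e[1]]) for e in edges}
    med = np.median(list(lengths.values()))
    m = np.zeros((n, n), bool)
    for (i, j), d in lengths.items():
        if d <= prune_factor * med:
            m[i, j] = m[j, i] = True
    names = [f"E{i + 1:02d}" for i in range(n)]
    return MontageAdjacency(names, m, pos)


# ---------------------------------------------------------------------------
# within-subject factorial ANOVA
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    """One ANOVA effect (main effect or interaction)."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    p_corrected: float | None = None
    level_means: dict = field(default_factory=dict)  # level -> (mean, sem)

    def as_dict(self) -> dict:
        return {"effect": self.effect, "F": self.F, "df1": self.df1,
                "df2": self.df2, "p": self.p,
                "p_corrected": (np.nan if self.p_corrected is None
                                else self.p_corrected),
                "partial_eta_sq": self.partial_eta_sq}


class AnovaResults:
    """Collection of :class:`EffectResult` with a summary table."""

    def __init__(self, effects: list[EffectResult], n_subjects: int,
                 factors: list[str]):
        self.effects = effects
        self.n_subjects = n_subjects
        self.factors = factors

    def __iter__(self):
        return iter(self.effects)

    def __getitem__(self, effect: str) -> EffectResult:
        for e in self.effects:
            if e.effect == effect:
                return e
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_dict() for e in self.effects])

    def summary(self) -> str:
        k = " x ".join(self.factors)
        head = (f"Within-subject ANOVA ({k}), n={self.n_subjects}\n"
                + "-" * 62 + "\n"
                + f"{'effect':<24}{'F':>9}{'df':>9}{'p':>11}{'pes':>8}\n")
        body = ""
        for e in self.effects:
            p = "<.001" if e.p < 0.001 else f"{e.p:.3f}"
            body += (f"{e.effect:<24}{e.F:>9.3f}{f'({e.df1},{e.df2})':>9}"
                     f"{p:>11}{e.partial_eta_sq:>8.3f}\n")
        return head + body


class WithinSubjectAnova:
    """Fully within-subject factorial ANOVA for 2-level factors.

    Parameters
    ----------
    data :
        Long-format DataFrame with one or more rows per subject x cell
        (rows within a cell are averaged first).
    dv, subject :
        Column names of the dependent variable and the subject identifier.
    within :
        Ordered list of 2-level factor columns.

    Each effect's F is computed from per-subject contrast scores with the
    +/-1 product coding of the participating factors: F = (mean/SE)^2 with
    df (1, n-1), and partial eta squared = F / (F + df2).
    """

    def __init__(self, data: pd.DataFrame, dv: str, subject: str,
                 within: list[str]):
        self.dv, self.subject, self.within = dv, subject, list(within)
        missing_cols = [c for c in [dv, subject, *within] if c not in data.columns]
        if missing_cols:
            raise InputError(f"missing columns: {missing_cols}")
        data = data[[subject, *self.within, dv]].copy()
        if data[dv].isna().any():
            bad = data[data[dv].isna()][[subject, *self.within]]
            raise DataError(f"missing (NaN) cells:\n{bad.to_string(index=False)}")
        cells = data.groupby([subject, *self.within], observed=True)[dv] \
                    .mean().reset_index()
        self.levels = {}
        for f in self.within:
            lv = sorted(cells[f].unique())
            if len(lv) != 2:
                raise InputError(f"factor {f!r} must have exactly 2 levels, "
                                 f"got {lv}")
            self.levels[f] = lv
        self.subjects = sorted(cells[subject].unique())
        n_cells = 2 ** len(self.within)
        counts = cells.groupby(subject, observed=True).size()
        if (counts != n_cells).any():
            bad = counts[counts != n_cells]
            raise DataError(
                f"unbalanced design; expected {n_cells} cells per subject, "
                f"got:\n{bad.to_string()}"
            )
        if len(self.subjects) < 2:
            raise InputError("need at least 2 subjects")
        # cell matrix: subjects x cells, with sign codes per factor
        wide = cells.pivot_table(index=subject, columns=self.within,
                                 values=dv, observed=True)
        wide = wide.reindex(self.subjects)
        self._cell_values = wide.to_numpy()
        self._cell_signs = np.array([
            [1.0 if lev == self.levels[f][1] else -1.0
             for f, lev in zip(self.within, (col if isinstance(col, tuple) else (col,)))]
            for col in wide.columns
        ])  # (n_cells, n_factors)
        self._cells_frame = cells

    def fit(self) -> AnovaResults:
        n = len(self.subjects)
        effects = []
        k = len(self.within)
        for mask in range(1, 2 ** k):
            members = [self.within[i] for i in range(k) if mask >> i & 1]
            signs = np.prod(
                self._cell_signs[:, [i for i in range(k) if mask >> i & 1]],
                axis=1,
            )
            # per-subject contrast: difference of the two marginal means
            scores = self._cell_values @ (signs / (len(signs) / 2.0))
            m, sd = scores.mean(), scores.std(ddof=1)
            if sd == 0:
                F = 0.0 if m == 0 else np.inf
            else:
                F = (m / (sd / np.sqrt(n))) ** 2
            p = float(sst.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
            pes = 1.0 if not np.isfinite(F) else F / (F + (n - 1))
            name = " x ".join(members)
            level_means = {}
            if len(members) == 1:
                f = members[0]
                col = self.within.index(f)
                for lev, s in zip(self.levels[f], (-1.0, 1.0)):
                    sel = self._cell_signs[:, col] == s
                    subj_means = self._cell_values[:, sel].mean(axis=1)
                    level_means[lev] = (float(subj_means.mean()),
                                        float(subj_means.std(ddof=1) / np.sqrt(n)))
            effects.append(EffectResult(
                effect=name, F=float(F), df1=1, df2=n - 1, p=p,
                partial_eta_sq=float(pes), level_means=level_means,
            ))
        return AnovaResults(effects, n, self.within)


def rm_anova(table: pd.DataFrame, dv: str = "exponent",
             subject: str = "participant",
             factors: list[str] = ("period", "drug", "prime", "flanker"),
             ) -> AnovaResults:
    """Fit a fully within-subject 2^k factorial ANOVA on a long table."""
    return WithinSubjectAnova(table, dv, subject, list(factors)).fit()


def follow_up_anovas(table: pd.DataFrame, split_by: str,
                     dv: str = "exponent", subject: str = "participant",
                     factors: list[str] | None = None,
                     ) -> dict[str, AnovaResults]:
    """Separate ANOVAs per level of ``split_by`` with Bonferroni correction.

    Reported ``p_corrected`` is min(1, m * p) where m is the number of
    levels of the splitting factor.
    """
    levels = sorted(table[split_by].unique())
    m = len(levels)
    if factors is None:
        factors = [c for c in ("period", "drug", "prime", "flanker")
                   if c in table.columns and c != split_by]
    out = {}
    for lev in levels:
        res = rm_anova(table[table[split_by] == lev], dv, subject, factors)
        for e in res.effects:
            e.p_corrected = min(1.0, m * e.p)
        out[lev] = res
    return out


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """One electrode cluster with its Monte-Carlo p-value."""

    electrodes: tuple[str, ...]
    mass: float
    p_value: float
    sign: str  # 'positive' | 'negative'

    @property
    def significant(self) -> bool:  # at the alpha stored by the parent test
        return self._significant

    _significant: bool = False


@dataclass
class ClusterTestResult:
    """Full output of a cluster-based permutation test."""

    clusters: list[ClusterResult]
    stat_map: np.ndarray
    threshold: float
    stat: str
    names: list[str]
    alpha: float
    n_permutations: int
    null_max_mass: np.ndarray

    @property
    def significant_clusters(self) -> list[ClusterResult]:
        return [c for c in self.clusters if c.p_value <= self.alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"electrodes": ",".join(c.electrodes), "n_electrodes":
                 len(c.electrodes), "mass": c.mass, "p_value": c.p_value,
                 "sign": c.sign,
                 "significant": c.p_value <= self.alpha}
                for c in self.clusters]
        return pd.DataFrame(rows, columns=["electrodes", "n_electrodes",
                                           "mass", "p_value", "sign",
                                           "significant"])


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Column-wise one-sample t of paired differences (n_subjects, n_elec)."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), np.where(m == 0, 0.0, np.inf))
    return t


def _find_clusters(mask: np.ndarray, neighbors: list[np.ndarray]) -> list[np.ndarray]:
    """Connected components of the suprathreshold electrode set (BFS)."""
    todo = set(np.flatnonzero(mask).tolist())
    clusters = []
    while todo:
        start = todo.pop()
        comp = [start]
        frontier = [start]
        while frontier:
            nxt = []
            for i in frontier:
                for j in neighbors[i]:
                    if j in todo:
                        todo.discard(int(j))
                        comp.append(int(j))
                        nxt.append(int(j))
            frontier = nxt
        clusters.append(np.array(sorted(comp)))
    return clusters


def _max_cluster_mass(stat_row: np.ndarray, thr: float, neighbors,
                      signed: bool) -> float:
    """Largest |cluster mass| in one permutation's statistic map."""
    best = 0.0
    if signed:
        for sgn in (1.0, -1.0):
            mask = sgn * stat_row > thr
            if mask.any():
                for comp in _find_clusters(mask, neighbors):
                    best = max(best, abs(stat_row[comp].sum()))
    else:
        mask = stat_row > thr
        if mask.any():
            for comp in _find_clusters(mask, neighbors):
                best = max(best, stat_row[comp].sum())
    return best


def cluster_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    adjacency: MontageAdjacency,
    stat: str = "F",
    sample_alpha: float | None = None,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterTestResult:
    """Electrode-space cluster-based permutation test on paired data.

    Parameters
    ----------
    a, b :
        (n_subjects, n_electrodes) paired condition arrays.
    stat :
        'F' (squared paired t, one-tailed threshold at ``sample_alpha``,
        default .005) or 'paired_t' (two-sided threshold at ``sample_alpha``,
        default .05, clusters formed separately per sign).
    n_permutations, alpha, seed :
        Monte-Carlo draws of within-subject sign flips, cluster-level
        significance level, and RNG seed.

    The null distribution is the maximum |cluster mass| over each
    permutation's statistic map; p = (1 + #{null >= observed}) /
    (1 + n_permutations), so p can never be 0 and ties count against
    significance.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise InputError("a and b must be (n_subjects, n_electrodes) and match")
    n_subj, n_elec = a.shape
    if n_subj < 2:
        raise InputError("need at least 2 subjects")
    if n_elec != adjacency.n:
        raise InputError("adjacency does not cover all electrodes")

    diffs = a - b
    n = n_subj
    t_obs = _paired_t(diffs)
    signed = stat == "paired_t"
    if stat == "F":
        sample_alpha = 0.005 if sample_alpha is None else sample_alpha
        thr = float(sst.f.ppf(1 - sample_alpha, 1, n - 1))
        stat_obs = t_obs ** 2
    elif stat == "paired_t":
        sample_alpha = 0.05 if sample_alpha is None else sample_alpha
        thr = float(sst.t.ppf(1 - sample_alpha / 2, n - 1))
        stat_obs = t_obs
    else:
        raise InputError(f"unknown stat {stat!r}")

    neighbors = adjacency.neighbors

    # observed clusters
    clusters: list[ClusterResult] = []
    obs = []
    if signed:
        for sgn, name in ((1.0, "positive"), (-1.0, "negative")):
            mask = sgn * stat_obs > thr
            for comp in _find_clusters(mask, neighbors):
                obs.append((comp, float(stat_obs[comp].sum()), name))
    else:
        mask = stat_obs > thr
        for comp in _find_clusters(mask, neighbors):
            obs.append((comp, float(stat_obs[comp].sum()), "positive"))

    # permutation null of the maximum |cluster mass|, vectorized t maps
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_subj))
    perm_mean = signs @ diffs / n
    ss = (diffs ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        perm_var = (ss[None, :] - n * perm_mean ** 2) / (n - 1)
        perm_var = np.maximum(perm_var, 0.0)
        perm_t = np.where(perm_var > 0, perm_mean / np.sqrt(perm_var / n),
                          np.where(perm_mean == 0, 0.0, np.inf))
    perm_stat = perm_t if signed else perm_t ** 2
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _max_cluster_mass(perm_stat[i], thr, neighbors, signed)

    for comp, mass, name in obs:
        p = float((1 + np.sum(null >= abs(mass))) / (1 + n_permutations))
        cr = ClusterResult(
            electrodes=tuple(adjacency.names[i] for i in comp),
            mass=mass, p_value=p, sign=name,
        )
        cr._significant = p <= alpha
        clusters.append(cr)
    clusters.sort(key=lambda c: c.p_value)
    return ClusterTestResult(
        clusters=clusters, stat_map=stat_obs, threshold=thr, stat=stat,
        names=list(adjacency.names), alpha=alpha,
        n_permutations=n_permutations, null_max_mass=null,
    )


def electrodewise_condition_tests(
    table: pd.DataFrame,
    adjacency: MontageAdjacency,
    contrast: tuple[str, str, str] = ("drug", "mph", "placebo"),
    stat: str = "paired_t",
    sample_alpha: float | None = None,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict[tuple, ClusterTestResult]:
    """Cluster tests of a paired contrast per prime x flanker x period map.

    For each of the 4 prime x flanker combinations and each period, the
    contrast (default MPH - placebo) is tested electrode-wise with the
    cluster-based permutation test; returns a dict keyed by
    (prime, flanker, period).
    """
    factor, lev_a, lev_b = contrast
    results = {}
    keys = table[["prime", "flanker", "period"]].drop_duplicates()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(keys))
    for (row, child) in zip(keys.itertuples(index=False), child_seeds):
        sub = table[(table["prime"] == row.prime)
                    & (table["flanker"] == row.flanker)
                    & (table["period"] == row.period)]
        wide_a = sub[sub[factor] == lev_a].pivot(
            index="participant", columns="electrode", values="exponent")
        wide_b = sub[sub[factor] == lev_b].pivot(
            index="participant", columns="electrode", values="exponent")
        wide_b = wide_b.reindex(index=wide_a.index, columns=wide_a.columns)
        order = [n for n in adjacency.names if n in wide_a.columns]
        if len(order) != adjacency.n:
            raise InputError("table does not cover every montage electrode")
        res = cluster_permutation_test(
            wide_a[order].to_numpy(), wide_b[order].to_numpy(), adjacency,
            stat=stat, sample_alpha=sample_alpha,
            n_permutations=n_permutations, alpha=alpha, seed=int(child),
        )
        results[(row.prime, row.flanker, row.period)] = res
    return results
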