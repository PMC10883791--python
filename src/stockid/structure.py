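"""Population structure: PCA, pairwise Weir-Cockerham F_ST with bootstrap,
isolation-by-distance model selection by AICc, two-level AMOVA, and
directional relative migration from migrant-pool G_ST.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypeMatrix

__all__ = [
    "FstMatrix", "IbdFit", "AmovaResult", "MigrationGraph",
    "pca_genotypes", "weir_cockerham_components", "multilocus_theta",
    "pairwise_fst", "ibd_fit", "aicc", "amova_two_level", "div_migrate",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _impute_standardize(dosage: np.ndarray, scale: bool = True
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages per locus, center, optionally unit-scale.

    Returns the transformed matrix and the boolean mask of retained
    (non-constant, not-all-missing) loci.
    """
    d = dosage.astype(float)
    d[dosage == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    if np.isnan(mean).any():
        raise ValueError("locus with no called genotypes")
    idx = np.where(np.isnan(d))
    d[idx] = mean[idx[1]]
    d -= mean
    sd = d.std(axis=0)
    keep = sd > 0
    d = d[:, keep]
    if scale:
        d /= sd[keep]
    return d, keep


def pca_genotypes(gm: GenotypeMatrix, n_axes: int = 10) -> dict:
    """PCA of the genotype matrix (missing mean-imputed, loci unit-scaled).

    Returns scores (n_samples x k), loadings (n_loci_kept x k), explained
    variance fractions, eigenvalues, and the mask of loci used.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    x, keep = _impute_standardize(gm.dosage)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_axes, len(s))
    eig = s ** 2 / max(gm.n_samples - 1, 1)
    return {
        "scores": u[:, :k] * s[:k],
        "loadings": vt[:k].T,
        "explained": eig[:k] / eig.sum(),
        "eigenvalues": eig,
        "loci_used": keep,
    }


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def weir_cockerham_components(gm: GenotypeMatrix, labels: np.ndarray | None = None
                              ) -> pd.DataFrame:
    """Per-locus WC-84 variance components a (among), b (between individuals
    within populations), c (within individuals) for the populations defined
    by ``labels`` (defaults to the sample group column).

    Loci with fewer than two populations containing called genotypes, or
    monomorphic across all of them, get NaN components and are excluded by
    :func:`multilocus_theta`.
    """
    labels = gm.groups if labels is None else np.asarray(labels)
    pops = pd.unique(labels)
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")

    called = gm.called
    d = gm.dosage
    n_i = np.empty((r, gm.n_loci))
    p_i = np.empty((r, gm.n_loci))
    h_i = np.empty((r, gm.n_loci))
    for k, pop in enumerate(pops):
        mask = labels == pop
        c = called[mask]
        n_i[k] = c.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n_i[k] > 0,
                              np.where(c, d[mask], 0).sum(axis=0) / (2 * n_i[k]),
                              np.nan)
            h_i[k] = np.where(n_i[k] > 0,
                              np.where(c, d[mask] == 1, False).sum(axis=0) / n_i[k],
                              np.nan)

    valid = (n_i > 0).sum(axis=0) >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        n_use = np.where(n_i > 0, n_i, 0.0)
        r_eff = (n_i > 0).sum(axis=0).astype(float)
        n_tot = n_use.sum(axis=0)
        nbar = n_tot / r_eff
        nc = (n_tot - (n_use ** 2).sum(axis=0) / n_tot) / (r_eff - 1)
        pbar = np.nansum(n_use * p_i, axis=0) / n_tot
        s2 = np.nansum(n_use * (p_i - pbar) ** 2, axis=0) / ((r_eff - 1) * nbar)
        hbar = np.nansum(n_use * h_i, axis=0) / n_tot

        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r_eff - 1) / r_eff
                                 - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r_eff - 1) / r_eff
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c_comp = hbar / 2.0

    mono = (pbar <= 0) | (pbar >= 1)
    bad = ~valid | mono | (nbar <= 1)
    for arr in (a, b, c_comp):
        arr[bad] = np.nan
    return pd.DataFrame({"chrom": gm.loci["chrom"], "pos": gm.loci["pos"],
                         "a": a, "b": b, "c": c_comp})


def multilocus_theta(components: pd.DataFrame) -> float:
    """Ratio-of-sums multilocus theta = sum(a) / sum(a + b + c)."""
    ok = components[["a", "b", "c"]].notna().all(axis=1)
    a = components.loc[ok, "a"].to_numpy()
    s = (components.loc[ok, ["a", "b", "c"]].to_numpy()).sum()
    if s == 0:
        return np.nan
    return float(a.sum() / s)


@dataclass
class FstMatrix:
    """Pairwise multilocus theta with percentile bootstrap CIs and p-values."""

    groups: list[str]
    theta: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    p_value: pd.DataFrame
    n_loci: pd.DataFrame

    def pairs(self) -> pd.DataFrame:
        rows = []
        for a, b in combinations(self.groups, 2):
            rows.append({"pop_a": a, "pop_b": b,
                         "theta": self.theta.loc[a, b],
                         "ci_low": self.ci_low.loc[a, b],
                         "ci_high": self.ci_high.loc[a, b],
                         "p_value": self.p_value.loc[a, b],
                         "n_loci": self.n_loci.loc[a, b]})
        return pd.DataFrame(rows)


def pairwise_fst(gm: GenotypeMatrix, n_boot: int = 1000, seed: int = 0,
                 two_sided: bool = False) -> FstMatrix:
    """Pairwise multilocus WC-84 theta among sample groups.

    The bootstrap resamples loci; the CI is the 2.5-97.5 percentile interval
    and the p-value the one-sided fraction of bootstrap replicates at or
    below zero (or its two-sided doubling when requested).
    """
    groups = sorted(pd.unique(gm.groups))
    k = len(groups)
    theta = pd.DataFrame(0.0, index=groups, columns=groups)
    lo = theta.copy()
    hi = theta.copy()
    pv = theta.copy()
    nl = pd.DataFrame(0, index=groups, columns=groups)
    rng = np.random.default_rng(seed)

    for a, b in combinations(groups, 2):
        mask = np.isin(gm.groups, (a, b))
        sub = gm.take(sample_idx=mask)
        comp = weir_cockerham_components(sub)
        ok = comp[["a", "b", "c"]].notna().all(axis=1)
        av = comp.loc[ok, "a"].to_numpy()
        tot = comp.loc[ok, ["a", "b", "c"]].to_numpy().sum(axis=1)
        L = len(av)
        t = float(av.sum() / tot.sum())
        idx = rng.integers(0, L, size=(n_boot, L))
        with np.errstate(invalid="ignore", divide="ignore"):
            boots = av[idx].sum(axis=1) / tot[idx].sum(axis=1)
        q_lo, q_hi = np.nanpercentile(boots, [2.5, 97.5])
        p = float(np.mean(boots <= 0.0))
        if two_sided:
            p = min(1.0, 2.0 * min(p, np.mean(boots >= 0.0)))
        theta.loc[a, b] = theta.loc[b, a] = t
        lo.loc[a, b] = lo.loc[b, a] = min(q_lo, t)
        hi.loc[a, b] = hi.loc[b, a] = max(q_hi, t)
        pv.loc[a, b] = pv.loc[b, a] = p
        nl.loc[a, b] = nl.loc[b, a] = L
    np.fill_diagonal(pv.values, np.nan)
    return FstMatrix(groups, theta, lo, hi, pv, nl)


# ---------------------------------------------------------------------------
# isolation by distance
# ---------------------------------------------------------------------------

def aicc(rss: float, n: int, k: int) -> float:
    """AICc for a Gaussian model with RSS, n observations and k parameters
    (k counts regression coefficients plus the residual variance)."""
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class IbdFit:
    model: str
    exclude: tuple[str, ...]
    n_pairs: int
    coefficients: dict[str, float]
    rss: float
    adj_r2: float
    slope_p: float
    aicc: float


def ibd_fit(fst: FstMatrix, dist: pd.DataFrame,
            exclude: tuple[str, ...] = ()) -> list[IbdFit]:
    """Fit linearized-F_ST ~ distance and null models; rank ascending by AICc.

    The response is theta/(1-theta) per population pair; the null model is
    the literal zero-mean model (residuals = response).  An intercept-only
    model is also reported for reference.  A pair with theta = 1 has an
    infinite response and is rejected.
    """
    groups = [g for g in fst.groups if g not in exclude]
    if len(groups) < 3:
        raise ValueError("need at least three populations after exclusion")
    missing = set(groups) - set(dist.index)
    if missing:
        raise ValueError(f"distance matrix lacks groups {missing}")
    y, x = [], []
    for a, b in combinations(groups, 2):
        t = fst.theta.loc[a, b]
        if t >= 1.0:
            raise ValueError(f"theta = 1 for pair ({a}, {b}): linearized F_ST undefined")
        y.append(t / (1.0 - t))
        x.append(float(dist.loc[a, b]))
    y = np.asarray(y)
    x = np.asarray(x)
    n = len(y)

    fits: list[IbdFit] = []
    lr = stats.linregress(x, y)
    resid = y - (lr.intercept + lr.slope * x)
    rss = float((resid ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    adj_r2 = 1.0 - (1.0 - (1.0 - rss / tss)) * (n - 1) / (n - 2) if tss > 0 else np.nan
    fits.append(IbdFit("linear", exclude, n,
                       {"intercept": lr.intercept, "slope": lr.slope},
                       rss, adj_r2, float(lr.pvalue), aicc(rss, n, 3)))
    rss0 = float((y ** 2).sum())
    fits.append(IbdFit("null", exclude, n, {}, rss0, np.nan, np.nan,
                       aicc(rss0, n, 1)))
    rss_m = tss
    fits.append(IbdFit("intercept_only", exclude, n, {"intercept": y.mean()},
                       rss_m, 0.0, np.nan, aicc(rss_m, n, 2)))
    return sorted(fits, key=lambda f: f.aicc)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Two-level nested AMOVA: variance partition with permutation p-values."""

    strata: pd.DataFrame   # source, df, ss, variance, pct, p_value

    def __post_init__(self) -> None:
        pct = self.strata["pct"].sum()
        if abs(pct - 100.0) > 0.01:
            raise ValueError(f"percentages sum to {pct}, expected 100")


def _nested_ss(x: np.ndarray, prim: np.ndarray, sec: np.ndarray
               ) -> tuple[float, float, float, float]:
    """Sums of squares for total / among-primary / among-secondary-within /
    within-secondary on Euclidean feature vectors (centroid identity)."""
    grand = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_wp = 0.0   # within primary
    ss_ws = 0.0   # within secondary
    for g in pd.unique(prim):
        xg = x[prim == g]
        ss_wp += float(((xg - xg.mean(axis=0)) ** 2).sum())
    for s in pd.unique(sec):
        xs = x[sec == s]
        ss_ws += float(((xs - xs.mean(axis=0)) ** 2).sum())
    ss_ag = ss_total - ss_wp           # among primary groups
    ss_as = ss_wp - ss_ws              # among secondary within primary
    return ss_total, ss_ag, ss_as, ss_ws


def _components(x: np.ndarray, prim: np.ndarray, sec: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Variance components (sigma_a, sigma_b, sigma_c) and the df/SS arrays
    for the unbalanced two-level nested design."""
    n_tot = len(prim)
    prim_u = pd.unique(prim)
    sec_u = pd.unique(sec)
    g = len(prim_u)
    s = len(sec_u)
    _, ss_ag, ss_as, ss_ws = _nested_ss(x, prim, sec)
    df = np.array([g - 1, s - g, n_tot - s], dtype=float)
    if (df <= 0).any():
        raise ValueError("degenerate design: zero degrees of freedom in a stratum")

    n_s = pd.Series(sec).value_counts()
    n_g = pd.Series(prim).value_counts()
    sec_of = {}
    for sv, pv in zip(sec, prim):
        sec_of[sv] = pv
    sum_ns2_over_ng = sum(
        sum(n_s[sv] ** 2 for sv in sec_u if sec_of[sv] == pv) / n_g[pv]
        for pv in prim_u)
    sum_ns2 = float((n_s ** 2).sum())
    sum_ng2 = float((n_g ** 2).sum())
    n1 = (n_tot - sum_ns2_over_ng) / (s - g)
    n2 = (sum_ns2_over_ng - sum_ns2 / n_tot) / (g - 1)
    n3 = (n_tot - sum_ng2 / n_tot) / (g - 1)

    sigma_c = ss_ws / df[2]
    sigma_b = (ss_as / df[1] - sigma_c) / n1
    sigma_a = (ss_ag / df[0] - sigma_c - n2 * sigma_b) / n3
    return (np.array([sigma_a, sigma_b, sigma_c]), df,
            np.array([ss_ag, ss_as, ss_ws]))


def amova_two_level(gm: GenotypeMatrix, primary: str, secondary: str,
                    n_perm: int = 1000, seed: int = 0) -> AmovaResult:
    """Nested AMOVA on mean-imputed dosage vectors (squared Euclidean distance).

    ``primary`` and ``secondary`` name columns of ``gm.samples``; every
    secondary stratum is the combination (primary, secondary) so a secondary
    label may recur across primary groups without ambiguity.  Permutations:
    whole secondary units are shuffled across primary groups for the
    among-primary test, and samples are shuffled across secondary units
    within each primary group for the among-secondary test.
    """
    prim = gm.samples[primary].to_numpy().astype(str)
    sec_raw = gm.samples[secondary].to_numpy().astype(str)
    if pd.isna(gm.samples[primary]).any() or pd.isna(gm.samples[secondary]).any():
        raise ValueError("every sample must be labeled for both factors")
    sec = np.char.add(np.char.add(prim, "/"), sec_raw)

    x, _ = _impute_standardize(gm.dosage, scale=False)
    sig, df, ss = _components(x, prim, sec)
    total = sig.sum()
    pct = 100.0 * sig / total

    rng = np.random.default_rng(seed)
    exceed = np.zeros(3)
    sec_units = pd.unique(sec)
    unit_prim = {u: u.split("/", 1)[0] for u in sec_units}
    for _ in range(n_perm):
        # among-primary: permute secondary units across primary labels
        perm_map = dict(zip(sec_units,
                            rng.permutation([unit_prim[u] for u in sec_units])))
        prim_p = np.array([perm_map[u] for u in sec])
        try:
            sig_a = _components(x, prim_p, sec)[0][0]
        except ValueError:
            sig_a = np.inf
        exceed[0] += sig_a >= sig[0]
        # among-secondary within primary: permute samples within primary
        sec_p = sec.copy()
        for g in pd.unique(prim):
            idx = np.flatnonzero(prim == g)
            sec_p[idx] = sec[idx][rng.permutation(len(idx))]
        sig_b = _components(x, prim, sec_p)[0][1]
        exceed[1] += sig_b >= sig[1]
        # within: permute everything (tests residual stratum; reported for completeness)
        perm = rng.permutation(len(prim))
        sig_c = _components(x, prim[perm], sec[perm])[0][2]
        exceed[2] += sig_c <= sig[2]
    pvals = (exceed + 1) / (n_perm + 1)

    strata = pd.DataFrame({
        "source": [f"between {primary}",
                   f"between {secondary} within {primary}",
                   f"within {secondary}"],
        "df": df.astype(int),
        "ss": ss,
        "variance": sig,
        "pct": pct,
        "p_value": pvals,
    })
    return AmovaResult(strata=strata)


# ---------------------------------------------------------------------------
# directional relative migration
# ---------------------------------------------------------------------------

@dataclass
class MigrationGraph:
    """Directed relative-migration matrix normalized to max 1."""

    groups: list[str]
    m: pd.DataFrame
    ci_low: pd.DataFrame | None = None
    ci_high: pd.DataFrame | None = None
    statistic: str = "Gst"

    def edges(self) -> pd.DataFrame:
        rows = []
        for a in self.groups:
            for b in self.groups:
                if a != b:
                    rows.append({"from": a, "to": b, "m": self.m.loc[a, b]})
        return pd.DataFrame(rows)


def _gst_pool(p_pool: np.ndarray, p_pop: np.ndarray) -> float:
    """Multilocus Nei G_ST (ratio of sums over loci) between a migrant pool
    and one member population, treating the two as equal-weight demes."""
    ok = np.isfinite(p_pool) & np.isfinite(p_pop)
    pa, pb = p_pool[ok], p_pop[ok]
    pbar = (pa + pb) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = pa * (1.0 - pa) + pb * (1.0 - pb)
    denom = ht.sum()
    if denom <= 0:
        return 0.0
    return float((ht - hs).sum() / denom)


def _pool_freq(pa: np.ndarray, pb: np.ndarray, kind: str) -> np.ndarray:
    if kind == "arithmetic":
        return (pa + pb) / 2.0
    # normalized geometric mean per allele: the hypothetical migrant pool is
    # weighted toward alleles shared by both populations, which is what makes
    # the source population (whose alleles seeded the recipient) sit closer
    # to the pool than the admixed recipient
    g1 = np.sqrt(pa * pb)
    g0 = np.sqrt((1.0 - pa) * (1.0 - pb))
    with np.errstate(invalid="ignore", divide="ignore"):
        pool = g1 / (g1 + g0)
    return np.where(g1 + g0 > 0, pool, (pa + pb) / 2.0)


def div_migrate(gm: GenotypeMatrix, n_boot: int = 1000, seed: int = 0,
                flow_cap: float = 1e6, pool: str = "geometric"
                ) -> MigrationGraph:
    """Directional relative migration between all group pairs.

    For each pair a hypothetical migrant pool is formed (normalized
    geometric mean of the two allele-frequency vectors by default); the raw
    directional flow out of a population is ``((1/g) - 1) / 4`` where ``g``
    is its multilocus G_ST to the pool — the less differentiated member of
    the pair is the likelier origin, hence drives the larger flow.  The
    matrix is normalized by its maximum entry; bootstraps resample loci.
    """
    groups = sorted(pd.unique(gm.groups))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    freqs = {g: gm.alt_freq(gm.groups == g) for g in groups}
    L = gm.n_loci
    rng = np.random.default_rng(seed)

    def raw_matrix(locus_idx: np.ndarray) -> pd.DataFrame:
        m = pd.DataFrame(0.0, index=groups, columns=groups)
        for a, b in combinations(groups, 2):
            pa = freqs[a][locus_idx]
            pb = freqs[b][locus_idx]
            pool_p = _pool_freq(pa, pb, pool)
            ga = _gst_pool(pool_p, pa)
            gb = _gst_pool(pool_p, pb)
            fa = ((1.0 / ga) - 1.0) / 4.0 if ga > 0 else flow_cap
            fb = ((1.0 / gb) - 1.0) / 4.0 if gb > 0 else flow_cap
            m.loc[a, b] = min(fa, flow_cap)   # flow a -> b driven by a-side g
            m.loc[b, a] = min(fb, flow_cap)
        return m

    all_idx = np.arange(L)
    raw = raw_matrix(all_idx)
    norm = raw / raw.values.max()
    lo = hi = None
    if n_boot:
        boots = np.empty((n_boot, len(groups), len(groups)))
        for i in range(n_boot):
            idx = rng.integers(0, L, size=L)
            b = raw_matrix(idx)
            boots[i] = (b / b.values.max()).values
        lo = pd.DataFrame(np.percentile(boots, 2.5, axis=0),
                          index=groups, columns=groups)
        hi = pd.DataFrame(np.percentile(boots, 97.5, axis=0),
                          index=groups, columns=groups)
    return MigrationGraph(groups, norm, lo, hi)
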