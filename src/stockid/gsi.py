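"""Genetic stock identification: informative-SNP panel construction balanced
on allele-frequency differences, Monte-Carlo cross-validated self-assignment,
Bayesian mixture estimation by Gibbs sampling, odds filtering, and
contribution summaries with inter-annual homogeneity tests.

Model sketch
------------
Reference allele frequencies per population are posterior means under a
Dirichlet(1/2) per-allele prior.  For a mixture individual *j* with genotype
g_jl at panel locus *l*, the likelihood of origin *i* is the product of
Hardy-Weinberg genotype probabilities at the reference frequencies (missing
genotypes are skipped).  The Gibbs sampler alternates

    z_j | pi  ~  Categorical( pi_i * L_ij )
    pi  | z   ~  Dirichlet( 1 + counts(z) )

and reports posterior mean mixing proportions and per-individual posterior
origin probabilities (mean of the z indicators after burn-in).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, AlleleFreqTable, GenotypeMatrix, allele_freq_table

__all__ = [
    "PanelSpec", "AssignmentCv", "MixtureResult",
    "afd_table", "build_balanced_panel", "self_assign_cv", "pick_panel",
    "mixture_estimate", "odds_filter", "contribution_summary",
]


# ---------------------------------------------------------------------------
# AFD panels
# ---------------------------------------------------------------------------

def afd_table(freqs: AlleleFreqTable) -> pd.DataFrame:
    """Absolute alt-allele frequency difference for every population pair.

    Returns a DataFrame indexed like ``freqs.loci`` with one column per pair
    ``"A|B"`` (pairs in lexicographic order).  Loci uncalled in either
    population get NaN.
    """
    cols = {}
    for a, b in combinations(sorted(freqs.pops), 2):
        cols[f"{a}|{b}"] = np.abs(freqs.freqs[freqs.pop_index(a)]
                                  - freqs.freqs[freqs.pop_index(b)])
    return pd.DataFrame(cols)


@dataclass
class PanelSpec:
    """Ranked per-pair locus lists with balanced sums of squared AFD."""

    target_size: int
    pair_lists: dict[str, list[int]]       # pair -> locus indices in pick order
    pair_sums: dict[str, float]            # pair -> sum of AFD^2
    union: list[int]                       # deduplicated union, deterministic order
    loci: pd.DataFrame

    def union_loci(self) -> pd.DataFrame:
        return self.loci.iloc[self.union]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair, lst in self.pair_lists.items():
            for rank, idx in enumerate(lst, start=1):
                rows.append({"pair": pair, "rank": rank,
                             "chrom": self.loci.iloc[idx]["chrom"],
                             "pos": self.loci.iloc[idx]["pos"],
                             "locus_index": idx})
        return pd.DataFrame(rows)


def build_balanced_panel(freqs: AlleleFreqTable, target_size: int) -> PanelSpec:
    """Greedy water-filling panel: per pair, loci ranked by decreasing AFD;
    at each step the pair with the smallest running sum of squared AFDs
    appends its next-best locus, so all pair sums stay balanced within one
    appended AFD^2.  Ties break lexicographically (pair name, then locus
    (chrom, pos) order).  A locus already in the union still accrues to
    another pair's list and sum; the loop stops when the deduplicated union
    reaches ``target_size`` or every pair is exhausted.
    """
    n_loci = len(freqs.loci)
    if target_size > n_loci:
        raise ValueError(f"target {target_size} exceeds {n_loci} available loci")
    table = afd_table(freqs)
    pairs = list(table.columns)

    ranked: dict[str, np.ndarray] = {}
    for pair in pairs:
        afd = table[pair].to_numpy()
        order = np.lexsort((np.arange(n_loci), -np.nan_to_num(afd, nan=-1.0)))
        order = order[np.isfinite(afd[order])]
        ranked[pair] = order

    pair_lists: dict[str, list[int]] = {p: [] for p in pairs}
    pair_sums: dict[str, float] = {p: 0.0 for p in pairs}
    pointers: dict[str, int] = {p: 0 for p in pairs}
    frozen: set[str] = set()
    union: list[int] = []
    in_union: set[int] = set()

    while len(union) < target_size:
        active = [p for p in pairs if p not in frozen]
        if not active:
            warnings.warn("all pairs exhausted before reaching target size")
            break
        pick = min(active, key=lambda p: (pair_sums[p], p))
        ptr = pointers[pick]
        if ptr >= len(ranked[pick]):
            frozen.add(pick)
            warnings.warn(f"pair {pick!r} exhausted its loci; frozen")
            continue
        locus = int(ranked[pick][ptr])
        pointers[pick] = ptr + 1
        pair_lists[pick].append(locus)
        pair_sums[pick] += float(table[pick].iloc[locus] ** 2)
        if locus not in in_union:
            in_union.add(locus)
            union.append(locus)
    return PanelSpec(target_size=target_size, pair_lists=pair_lists,
                     pair_sums=pair_sums, union=union, loci=freqs.loci.copy())


# ---------------------------------------------------------------------------
# HWE log-likelihood classifier
# ---------------------------------------------------------------------------

def _smoothed_freqs(gm: GenotypeMatrix, sample_mask: np.ndarray,
                    locus_idx: np.ndarray) -> dict[str, np.ndarray]:
    """Per-population alt frequencies with +0.5 added to each allele count."""
    labels = gm.groups[sample_mask]
    d = gm.dosage[np.ix_(np.flatnonzero(sample_mask), locus_idx)]
    out = {}
    for pop in sorted(pd.unique(labels)):
        dd = d[labels == pop]
        called = dd != MISSING
        alt = np.where(called, dd, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        out[pop] = (alt + 0.5) / (tot + 1.0)
    return out


def _hwe_loglik(dosage: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Sum over loci of log HWE genotype probabilities; missing skipped.
    ``dosage``: (n, L); ``p``: (L,).  Returns (n,)."""
    logp = np.log(p)
    logq = np.log1p(-p)
    ll = np.select(
        [dosage == 0, dosage == 1, dosage == 2],
        [2.0 * logq, np.log(2.0) + logp + logq, 2.0 * logp],
        default=0.0)
    return ll.sum(axis=1)


def _assign(gm_test: np.ndarray, freqs: dict[str, np.ndarray]) -> np.ndarray:
    pops = sorted(freqs)
    ll = np.stack([_hwe_loglik(gm_test, freqs[p]) for p in pops], axis=1)
    return np.asarray(pops)[np.argmax(ll, axis=1)]


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validated self-assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentCv:
    train_props: tuple[float, ...]
    loci_props: tuple[float, ...]
    n_iter: int
    accuracy: pd.DataFrame     # columns: train_prop, loci_prop, iteration, population, accuracy, n_test
    confusion: pd.DataFrame    # true x assigned counts accumulated over everything

    def per_population(self) -> pd.DataFrame:
        return (self.accuracy.groupby(["train_prop", "loci_prop", "population"])
                ["accuracy"].agg(["mean", "std"]).reset_index())


def self_assign_cv(gm: GenotypeMatrix, panel: np.ndarray | None = None,
                   train_props: tuple[float, ...] = (0.7, 0.9),
                   loci_props: tuple[float, ...] = (0.5, 1.0),
                   n_iter: int = 100, seed: int = 0) -> AssignmentCv:
    """Monte-Carlo cross-validated self-assignment of reference individuals.

    Per iteration a stratified random fraction of each population trains the
    HWE log-likelihood classifier (allele counts +0.5 smoothed), optionally
    on a random subset of the panel loci; the held-out individuals are
    assigned to the maximum-likelihood population.
    """
    pops = sorted(pd.unique(gm.groups))
    counts = pd.Series(gm.groups).value_counts()
    if len(pops) < 2 or (counts < 3).any():
        raise ValueError("need >= 2 populations with >= 3 samples each")
    base_loci = (np.arange(gm.n_loci) if panel is None
                 else np.asarray(panel, dtype=int))
    rng = np.random.default_rng(seed)

    acc_rows = []
    confusion = pd.DataFrame(0, index=pops, columns=pops)
    for it in range(n_iter):
        for tp in train_props:
            train_mask = np.zeros(gm.n_samples, dtype=bool)
            for pop in pops:
                idx = np.flatnonzero(gm.groups == pop)
                n_train = max(int(round(tp * len(idx))), 1)
                n_train = min(n_train, len(idx) - 1)
                train_mask[rng.choice(idx, size=n_train, replace=False)] = True
            for lp in loci_props:
                if lp >= 1.0:
                    loci = base_loci
                else:
                    k = max(int(round(lp * len(base_loci))), 1)
                    loci = rng.choice(base_loci, size=k, replace=False)
                freqs = _smoothed_freqs(gm, train_mask, loci)
                test_idx = np.flatnonzero(~train_mask)
                assigned = _assign(gm.dosage[np.ix_(test_idx, loci)], freqs)
                truth = gm.groups[test_idx]
                for pop in pops:
                    m = truth == pop
                    if m.sum() == 0:
                        continue
                    acc_rows.append({"train_prop": tp, "loci_prop": lp,
                                     "iteration": it, "population": pop,
                                     "accuracy": float((assigned[m] == pop).mean()),
                                     "n_test": int(m.sum())})
                for t, a in zip(truth, assigned):
                    confusion.loc[t, a] += 1
    return AssignmentCv(train_props=tuple(train_props),
                        loci_props=tuple(loci_props), n_iter=n_iter,
                        accuracy=pd.DataFrame(acc_rows), confusion=confusion)


def pick_panel(cv_by_size: dict[int, AssignmentCv]) -> int:
    """Choose the panel size maximizing the minimum per-population mean
    accuracy; ties break on smaller mean across-iteration SD, then on the
    smaller panel."""
    scored = []
    for size in sorted(cv_by_size):
        per_pop = cv_by_size[size].per_population()
        min_acc = per_pop["mean"].min()
        mean_sd = per_pop["std"].fillna(0.0).mean()
        scored.append((-min_acc, mean_sd, size))
    scored.sort()
    return scored[0][2]


# ---------------------------------------------------------------------------
# Bayesian mixture estimation
# ---------------------------------------------------------------------------

@dataclass
class MixtureResult:
    pops: list[str]
    posterior: pd.DataFrame        # index sample_id, columns pops; rows sum to 1
    proportions: pd.Series         # posterior mean mixing proportions
    trace: np.ndarray              # (n_kept_sweeps, n_pops) pi draws
    kept: pd.Series | None = None  # odds-filter verdict per individual
    all_missing: list[str] = field(default_factory=list)
    years: pd.Series | None = None


def mixture_estimate(ref: GenotypeMatrix, mix: GenotypeMatrix,
                     panel: np.ndarray | None = None, n_sweeps: int = 2000,
                     burn_in: int = 100, seed: int = 0) -> MixtureResult:
    """Bayesian mixture analysis of a mixed sample against reference populations.

    Reference frequencies are Dirichlet(1/2) posterior means from the
    reference genotypes; the Gibbs sampler (see module docstring) runs
    ``n_sweeps`` sweeps discarding ``burn_in``.  Individuals with no called
    panel genotypes keep a flat likelihood (posterior = prior) and are
    flagged in ``all_missing``.
    """
    if n_sweeps <= burn_in:
        raise ValueError("chain length must exceed burn-in")
    if panel is None:
        panel = np.arange(ref.n_loci)
    panel = np.asarray(panel, dtype=int)
    ref_keys = ref.loci.iloc[panel][["chrom", "pos"]]
    mix_keyed = mix.loci.reset_index().set_index(["chrom", "pos"])
    try:
        mix_panel = mix_keyed.loc[
            list(ref_keys.itertuples(index=False, name=None)), "index"].to_numpy()
    except KeyError as e:
        raise ValueError(f"panel loci missing from mixture matrix: {e}") from e

    pops = sorted(pd.unique(ref.groups))
    freqs = _smoothed_freqs(ref, np.ones(ref.n_samples, dtype=bool), panel)
    d = mix.dosage[:, mix_panel]
    log_l = np.stack([_hwe_loglik(d, freqs[p]) for p in pops], axis=1)
    all_missing = [mix.sample_ids[i] for i in
                   np.flatnonzero((d == MISSING).all(axis=1))]

    rng = np.random.default_rng(seed)
    n, k = log_l.shape
    pi = np.full(k, 1.0 / k)
    z_mean = np.zeros((n, k))
    trace = np.empty((n_sweeps - burn_in, k))
    log_l -= log_l.max(axis=1, keepdims=True)
    lik = np.exp(log_l)
    for sweep in range(n_sweeps):
        w = lik * pi
        w /= w.sum(axis=1, keepdims=True)
        # vectorized categorical draw per individual
        u = rng.random(n)[:, None]
        z = (w.cumsum(axis=1) < u).sum(axis=1)
        counts = np.bincount(z, minlength=k)
        pi = rng.dirichlet(1.0 + counts)
        if sweep >= burn_in:
            trace[sweep - burn_in] = pi
            z_mean[np.arange(n), z] += 1.0
    z_mean /= (n_sweeps - burn_in)

    posterior = pd.DataFrame(z_mean, index=mix.sample_ids, columns=pops)
    proportions = pd.Series(trace.mean(axis=0), index=pops)
    years = (mix.samples.set_index("id")["year"]
             if "year" in mix.samples else None)
    return MixtureResult(pops=pops, posterior=posterior,
                         proportions=proportions, trace=trace,
                         all_missing=all_missing, years=years)


def odds_filter(mr: MixtureResult, ratio: float = 10.0) -> MixtureResult:
    """Keep individuals whose top posterior origin probability is at least
    ``ratio`` times the second largest (inclusive at exactly ``ratio``)."""
    post = mr.posterior.to_numpy()
    part = np.sort(post, axis=1)
    top, second = part[:, -1], part[:, -2]
    kept = top >= ratio * second - 1e-12
    mr.kept = pd.Series(kept, index=mr.posterior.index)
    return mr


# ---------------------------------------------------------------------------
# contribution summaries
# ---------------------------------------------------------------------------

def _chi2_homogeneity(counts: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson chi-squared homogeneity test without continuity correction.
    Rows = years, columns = categories.  Returns (statistic, p, df)."""
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    obs = counts.to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 0.0, 1.0, 0
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p), int(dof)


def contribution_summary(mr: MixtureResult | None,
                         tactic_table: pd.DataFrame | None = None,
                         assignments: pd.DataFrame | None = None) -> dict:
    """Per-year contribution tables by assigned river and by tactic, with
    chi-squared inter-annual homogeneity tests.

    Either pass a (odds-filtered) :class:`MixtureResult`, or an explicit
    ``assignments`` frame with columns ``sample_id, year, river``.  The
    tactic table needs ``sample_id, tactic, year``; only tactic-identified
    fish (marine/estuarine) enter the tactic percentages.
    """
    if assignments is None:
        if mr is None:
            raise ValueError("need a MixtureResult or an assignments frame")
        keep = mr.kept if mr.kept is not None else pd.Series(
            True, index=mr.posterior.index)
        assigned = mr.posterior.idxmax(axis=1)
        assignments = pd.DataFrame({
            "sample_id": mr.posterior.index,
            "river": assigned.to_numpy(),
            "year": (mr.years.reindex(mr.posterior.index).to_numpy()
                     if mr.years is not None else "all"),
        })[keep.to_numpy()]
    if len(assignments) == 0 or assignments.groupby("year").size().min() == 0:
        raise ValueError("a year has zero kept individuals")

    river_counts = assignments.pivot_table(index="year", columns="river",
                                           values="sample_id", aggfunc="count",
                                           fill_value=0)
    river_pct = 100.0 * river_counts.div(river_counts.sum(axis=1), axis=0)
    chi2_r, p_r, df_r = _chi2_homogeneity(river_counts)

    out = {
        "river_counts": river_counts, "river_pct": river_pct,
        "river_chi2": chi2_r, "river_p": p_r, "river_df": df_r,
    }
    if tactic_table is not None:
        tt = tactic_table.copy()
        tt = tt[tt["tactic"].isin(["marine", "estuarine"])]
        tac_counts = tt.pivot_table(index="year", columns="tactic",
                                    values="sample_id", aggfunc="count",
                                    fill_value=0)
        tac_pct = 100.0 * tac_counts.div(tac_counts.sum(axis=1), axis=0)
        chi2_t, p_t, df_t = _chi2_homogeneity(tac_counts)
        out.update({"tactic_counts": tac_counts, "tactic_pct": tac_pct,
                    "tactic_chi2": chi2_t, "tactic_p": p_t, "tactic_df": df_t})
    return out
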