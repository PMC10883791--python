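"""Synthetic reference populations, mixture samples, and QC artifacts with known truth.

The generator emulates the product of a reduced-representation SNP study of
hierarchically structured river populations feeding a mixed-stock estuarine
fishery:

* allele frequencies drift down a rooted population tree under the
  Balding-Nichols model (child frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)
  per branch), which induces hierarchical F_ST and a true
  isolation-by-distance relation when branch lengths are read as distances;
* reference individuals are Binomial(2, p_pop) draws; mixture individuals
  draw their origin from per-year mixing proportions and then genotypes from
  that origin's frequencies;
* a weak polygenic life-history-tactic signal is planted as linked blocks
  of tag SNPs whose underlying haplotype-state frequency differs by delta
  between tactic groups (see :class:`TacticSignal`);
* artifacts mimic what QC must remove: negative-binomial read depth with a
  minimum calling depth, merged-paralog loci (read-wise sums of two loci),
  and planted near-duplicate kin pairs.

Every stage derives its randomness from the single ``SimConfig.seed`` via
``numpy.random.SeedSequence`` spawning, so runs are reproducible and stages
are independently perturbable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import MISSING, AlleleFreqTable, GenotypeMatrix, write_vcf

__all__ = [
    "PopNode", "YearDesign", "SimConfig", "TruthTable",
    "study_tree", "study_config",
    "simulate_reference", "simulate_mixture", "inject_artifacts",
    "write_study", "tree_distances",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PopNode:
    """Node of the rooted population tree.

    ``f`` is the Balding-Nichols drift parameter of the branch leading to this
    node (ignored at the root); ``km`` the geographic length of that branch in
    kilometres, used to derive the pairwise distance matrix.  Leaves carry
    population labels.
    """

    name: str
    f: float = 0.0
    km: float = 0.0
    children: list["PopNode"] = field(default_factory=list)

    def leaves(self) -> list["PopNode"]:
        if not self.children:
            return [self]
        out: list[PopNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def validate(self, _root: bool = True) -> None:
        if not _root and not (0.0 < self.f < 1.0):
            raise ValueError(f"branch F for {self.name!r} must be in (0, 1), got {self.f}")
        for c in self.children:
            c.validate(_root=False)


@dataclass
class YearDesign:
    """Mixture sampling design for one year."""

    year: str
    n: int
    origin_props: dict[str, float]          # population -> mixing proportion
    tactic_props: dict[str, dict[str, float]]  # population -> tactic -> proportion


@dataclass
class SimConfig:
    """Full parameterization of a synthetic study."""

    seed: int = 0
    n_loci: int = 5000
    chrom_layout: list[tuple[str, int]] = field(default_factory=list)  # (name, length bp)
    pop_tree: PopNode | None = None
    sample_sizes: dict[str, int] = field(default_factory=dict)
    mixture_design: list[YearDesign] = field(default_factory=list)
    tactic_loci: tuple[int, float] = (20, 0.25)     # (count, frequency shift delta)
    tactic_regions: int = 2          # linked blocks carrying the tactic signal
    tactic_tag_noise: float = 0.1    # per-haplotype mis-tagging rate within a block
    missing_model: tuple[float, float, int] = (20.0, 5.0, 3)  # mean depth, dispersion, min depth
    kin_pairs: int = 0
    kin_redraw: float = 0.02   # fraction of a kin twin's genotypes re-drawn
    dup_loci: int = 0
    maf_floor: float = 0.01
    ancestral_beta: float | None = 0.2   # Beta(a, a) spectrum; None = uniform
    distance_scale_km: float = 1.0   # km per unit branch length (km field already in km)

    def validate(self) -> None:
        if self.pop_tree is None:
            raise ValueError("pop_tree is required")
        self.pop_tree.validate()
        leaves = [l.name for l in self.pop_tree.leaves()]
        if len(leaves) < 2:
            raise ValueError("population tree must have at least two leaves")
        if set(self.sample_sizes) - set(leaves):
            raise ValueError("sample_sizes references unknown populations")
        if any(n <= 0 for n in self.sample_sizes.values()):
            raise ValueError("sample sizes must be positive")
        for yd in self.mixture_design:
            if yd.n <= 0:
                raise ValueError(f"year {yd.year!r} has non-positive n")
            s = sum(yd.origin_props.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"origin proportions for {yd.year!r} sum to {s}")
            for pop, tp in yd.tactic_props.items():
                st = sum(tp.values())
                if abs(st - 1.0) > 1e-9:
                    raise ValueError(
                        f"tactic proportions for {pop!r}/{yd.year!r} sum to {st}")
        cnt, delta = self.tactic_loci
        if not 0.0 <= delta <= 0.5:
            raise ValueError("tactic frequency shift delta must lie in [0, 0.5]")
        if cnt > self.n_loci:
            raise ValueError("more tactic loci than loci")
        if self.dup_loci > self.n_loci // 2:
            raise ValueError("dup_loci exceeds half the locus count")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")


@dataclass
class TruthTable:
    """Ground truth of a simulated study: per-sample origins, per-locus frequencies, artifacts."""

    samples: pd.DataFrame   # sample_id, origin, tactic, year, kin_of
    loci: pd.DataFrame      # chrom, pos, ancestral_freq, tactic_locus, dup_artifact
    pop_freqs: AlleleFreqTable | None = None
    kin_pairs: list[tuple[str, str]] = field(default_factory=list)
    tactic_signal: "TacticSignal | None" = None


# ---------------------------------------------------------------------------
# study-shaped defaults
# ---------------------------------------------------------------------------

def study_tree() -> PopNode:
    """The default 8-population hierarchy.

    Two river complexes (FEU-GEO and the Koksoak system MEL/GUE/DEL/CAN plus
    the nearby BAL) diverge from a common ancestor; GUE and DEL are nearly
    panmictic sisters; CAN is a strongly drifted population inside the
    Koksoak clade; NST is an old isolate.  Branch F values are tuned to the
    field's typical river-scale differentiation (pairwise F_ST spanning
    roughly 0.002-0.15); branch km lengths are proportional to drift so the
    tree encodes a true isolation-by-distance relation.
    """
    def leaf(name, f, km):
        return PopNode(name, f=f, km=km)

    koksoak = PopNode("KOKSOAK", f=0.010, km=120, children=[
        leaf("MEL", 0.008, 100),
        PopNode("GUEDEL", f=0.006, km=70, children=[
            leaf("GUE", 0.002, 25),
            leaf("DEL", 0.002, 25),
        ]),
        leaf("CAN", 0.090, 300),
        leaf("BAL", 0.012, 140),
    ])
    feugeo = PopNode("FEUGEO", f=0.015, km=180, children=[
        leaf("FEU", 0.010, 120),
        leaf("GEO", 0.010, 130),
    ])
    return PopNode("ROOT", children=[koksoak, feugeo, leaf("NST", 0.140, 900)])


def study_config(seed: int = 0, n_loci: int = 5000, n_chrom: int = 29,
                 full_mixture: bool = True) -> SimConfig:
    """Study-scale configuration: 8 source populations with the observed
    sample sizes, a two-year estuarine mixture (152 + 128 fish), ~29
    chromosomes, a 20-locus tactic signal, and modest QC artifacts."""
    chrom_layout = [(f"chr{i + 1:02d}", 40_000_000) for i in range(n_chrom)]
    sizes = {"FEU": 37, "MEL": 30, "GUE": 30, "DEL": 42, "CAN": 19,
             "BAL": 39, "GEO": 41, "NST": 10}
    # mixing proportions follow the fishery composition: the two productive
    # Koksoak tributaries dominate, with small MEL and CAN contributions
    origins_2020 = {"GUE": 0.291, "DEL": 0.616, "MEL": 0.020, "CAN": 0.073}
    origins_2021 = {"GUE": 0.349, "DEL": 0.587, "MEL": 0.040, "CAN": 0.024}
    tactics_2020 = {p: {"estuarine": 0.738, "marine": 0.262} for p in origins_2020}
    tactics_2021 = {p: {"estuarine": 0.468, "marine": 0.532} for p in origins_2021}
    mixture = [
        YearDesign("2020", 152, origins_2020, tactics_2020),
        YearDesign("2021", 128, origins_2021, tactics_2021),
    ] if full_mixture else []
    return SimConfig(seed=seed, n_loci=n_loci, chrom_layout=chrom_layout,
                     pop_tree=study_tree(), sample_sizes=sizes,
                     mixture_design=mixture, tactic_loci=(20, 0.25),
                     missing_model=(20.0, 5.0, 3), kin_pairs=4, dup_loci=25)


# ---------------------------------------------------------------------------
# simulation core
# ---------------------------------------------------------------------------

def _sub_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stage + 1)[stage])


def _locus_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    layout = config.chrom_layout or [("chr01", 50_000_000)]
    lengths = np.array([l for _, l in layout], dtype=float)
    per = rng.multinomial(config.n_loci, lengths / lengths.sum())
    rows = []
    bases = np.array(["A", "C", "G", "T"])
    for (chrom, length), k in zip(layout, per):
        pos = np.sort(rng.choice(np.arange(1, length, 50), size=k, replace=False))
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((chrom, int(p), bases[ref], bases[alt]))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _drift_down(node: PopNode, p: np.ndarray, rng: np.random.Generator,
                out: dict[str, np.ndarray]) -> None:
    for child in node.children:
        f = child.f
        a = p * (1.0 - f) / f
        b = (1.0 - p) * (1.0 - f) / f
        q = np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)
        if child.children:
            _drift_down(child, q, rng, out)
        else:
            out[child.name] = q


def _ancestral_freqs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Ancestral allele frequencies on [maf_floor, 1 - maf_floor].

    The default is a symmetric Beta(a, a) spectrum truncated to the MAF
    band (inverse-CDF sampling), which skews frequencies toward the
    extremes the way reduced-representation SNP panels do and yields a mean
    expected heterozygosity near 0.2; ``ancestral_beta=None`` gives the
    plain uniform spectrum.
    """
    lo, hi = config.maf_floor, 1.0 - config.maf_floor
    if config.ancestral_beta is None:
        return rng.uniform(lo, hi, config.n_loci)
    from scipy.stats import beta as beta_dist
    a = config.ancestral_beta
    c_lo, c_hi = beta_dist.cdf([lo, hi], a, a)
    u = rng.uniform(c_lo, c_hi, config.n_loci)
    return np.clip(beta_dist.ppf(u, a, a), lo, hi)


def _leaf_freqs(config: SimConfig, rng: np.random.Generator
                ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    ancestral = _ancestral_freqs(config, rng)
    freqs: dict[str, np.ndarray] = {}
    _drift_down(config.pop_tree, ancestral, rng, freqs)
    return ancestral, freqs


@dataclass
class TacticSignal:
    """Planted polygenic tactic signal: linked tag-SNP blocks of latent
    region haplotypes whose state frequency differs by delta between tactic
    groups.

    Each region holds a latent diallelic haplotype state with base frequency
    ``p_state``; estuarine and marine individuals draw their two copies at
    ``p_state +/- sign * delta / 2`` (on the effective marginal scale, i.e.
    the per-locus alt-frequency difference between tactic groups is delta,
    clipped to [0.01, 0.99]).  Tag SNPs copy the haplotype state with
    per-copy error ``eps``, which sets the within-block LD (r ~ (1-2 eps)^2).
    """

    regions: list[dict]   # {"loci": indices, "sign": +/-1, "p_state": float}
    delta: float
    eps: float

    def loci_idx(self) -> np.ndarray:
        if not self.regions:
            return np.empty(0, dtype=int)
        return np.concatenate([r["loci"] for r in self.regions])


def _plan_tactic_regions(config: SimConfig, loci: pd.DataFrame,
                         rng: np.random.Generator) -> TacticSignal:
    n_tac, delta = config.tactic_loci
    if n_tac == 0:
        return TacticSignal(regions=[], delta=delta, eps=config.tactic_tag_noise)
    n_regions = max(1, min(config.tactic_regions, n_tac))
    per = [n_tac // n_regions + (1 if i < n_tac % n_regions else 0)
           for i in range(n_regions)]
    chroms = loci["chrom"].to_numpy()
    counts = pd.Series(chroms).value_counts()
    eligible = [c for c in counts.index if counts[c] >= max(per)]
    if len(eligible) < n_regions:
        eligible = list(counts.index[:n_regions])
    n_regions = min(n_regions, len(eligible))
    per = [n_tac // n_regions + (1 if i < n_tac % n_regions else 0)
           for i in range(n_regions)]
    chosen = rng.choice(len(eligible), size=n_regions, replace=False)
    regions = []
    for m, ci in zip(per, chosen):
        on_chrom = np.flatnonzero(chroms == eligible[ci])
        idx = np.sort(rng.choice(on_chrom, size=min(m, len(on_chrom)),
                                 replace=False))
        regions.append({"loci": idx,
                        "sign": float(rng.choice([-1.0, 1.0])),
                        "p_state": float(rng.uniform(0.35, 0.65))})
    return TacticSignal(regions=regions, delta=delta,
                        eps=config.tactic_tag_noise)


_TACTIC_DIR = {"estuarine": 1.0, "marine": -1.0}


def _draw_tactic_block(rng: np.random.Generator, region: dict,
                       tactic: str | None, signal: TacticSignal) -> np.ndarray:
    """Genotypes at one region's tag loci for one individual."""
    eps = signal.eps
    direction = _TACTIC_DIR.get(tactic, 0.0) if tactic else 0.0
    shift = direction * region["sign"] * signal.delta / (2.0 * (1.0 - 2.0 * eps))
    a = float(np.clip(region["p_state"] + shift, 0.01, 0.99))
    copies = rng.random(2) < a
    probs = np.where(copies, 1.0 - eps, eps)
    m = len(region["loci"])
    alleles = rng.random((2, m)) < probs[:, None]
    return alleles.sum(axis=0).astype(np.int8)


def simulate_reference(config: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate the reference (source-population) genotype matrix.

    Allele frequencies drift down ``config.pop_tree`` under Balding-Nichols;
    each sample's genotypes are Binomial(2, p_pop) draws.  Populations with a
    tactic design in any mixture year receive tactic labels at the reference
    level too (equal mixture of the year-averaged tactic proportions); the
    planted tactic loci shift frequencies between tactic groups by delta.
    """
    config.validate()
    rng = _sub_rng(config.seed, 0)
    loci = _locus_positions(config, rng)
    ancestral, freqs = _leaf_freqs(config, rng)

    signal = _plan_tactic_regions(config, loci, rng)
    tactic_idx = signal.loci_idx()

    tactic_pops = sorted({p for yd in config.mixture_design for p in yd.tactic_props})
    ref_tactic_props: dict[str, dict[str, float]] = {}
    for p in tactic_pops:
        agg: dict[str, float] = {}
        k = 0
        for yd in config.mixture_design:
            if p in yd.tactic_props:
                k += 1
                for t, v in yd.tactic_props[p].items():
                    agg[t] = agg.get(t, 0.0) + v
        ref_tactic_props[p] = {t: v / k for t, v in agg.items()}

    rows, dosage_rows = [], []
    pops = sorted(config.sample_sizes)
    for pop in pops:
        n = config.sample_sizes[pop]
        p = freqs[pop]
        if pop in ref_tactic_props:
            tacs = list(ref_tactic_props[pop])
            probs = np.array([ref_tactic_props[pop][t] for t in tacs])
            draw = rng.choice(len(tacs), size=n, p=probs)
            tactics = [tacs[i] for i in draw]
        else:
            tactics = [None] * n
        for i in range(n):
            t = tactics[i]
            g = rng.binomial(2, p).astype(np.int8)
            for region in signal.regions:
                g[region["loci"]] = _draw_tactic_block(rng, region, t, signal)
            dosage_rows.append(g)
            rows.append({"id": f"{pop}_{i + 1:03d}", "group": pop,
                         "tactic": t, "year": None})

    samples = pd.DataFrame(rows)
    gm = GenotypeMatrix(dosage=np.vstack(dosage_rows), loci=loci, samples=samples)

    pop_freqs = AlleleFreqTable(
        pops=pops, loci=loci.copy(),
        freqs=np.vstack([freqs[p] for p in pops]),
        n_called=np.full((len(pops), config.n_loci), 10**9))
    truth_loci = loci.copy()
    truth_loci["ancestral_freq"] = ancestral
    truth_loci["tactic_locus"] = False
    truth_loci.loc[tactic_idx, "tactic_locus"] = True
    truth_loci["tactic_region"] = -1
    for ri, region in enumerate(signal.regions):
        truth_loci.loc[region["loci"], "tactic_region"] = ri
    truth_loci["dup_artifact"] = False
    truth_samples = samples.rename(columns={"id": "sample_id", "group": "origin"})
    truth_samples["kin_of"] = None
    return gm, TruthTable(samples=truth_samples, loci=truth_loci,
                          pop_freqs=pop_freqs, tactic_signal=signal)


def simulate_mixture(config: SimConfig, ref_freqs: AlleleFreqTable,
                     truth: TruthTable | None = None
                     ) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate the mixed-stock (estuary) samples from reference frequencies.

    Each fish draws a true origin from its year's mixing proportions, a
    tactic from that origin's tactic proportions, and genotypes
    Binomial(2, p_origin) with the planted tactic shift applied.
    """
    config.validate()
    if not config.mixture_design:
        raise ValueError("config has no mixture design")
    for yd in config.mixture_design:
        missing = set(yd.origin_props) - set(ref_freqs.pops)
        if missing:
            raise ValueError(f"origin proportions reference unknown pops {missing}")
    rng = _sub_rng(config.seed, 1)

    signal = (truth.tactic_signal if truth is not None and truth.tactic_signal
              else TacticSignal([], config.tactic_loci[1],
                                config.tactic_tag_noise))

    rows, dosage_rows = [], []
    counter = 0
    for yd in config.mixture_design:
        pops = sorted(yd.origin_props)
        probs = np.array([yd.origin_props[p] for p in pops])
        origins = rng.choice(len(pops), size=yd.n, p=probs)
        for o in origins:
            pop = pops[o]
            p = ref_freqs.freqs[ref_freqs.pop_index(pop)]
            tp = yd.tactic_props.get(pop)
            if tp:
                tacs = list(tp)
                t = tacs[rng.choice(len(tacs), p=np.array([tp[x] for x in tacs]))]
            else:
                t = None
            counter += 1
            g = rng.binomial(2, np.clip(p, 0, 1)).astype(np.int8)
            for region in signal.regions:
                g[region["loci"]] = _draw_tactic_block(rng, region, t, signal)
            dosage_rows.append(g)
            rows.append({"id": f"MIX_{yd.year}_{counter:03d}", "group": "MIX",
                         "tactic": t, "year": yd.year, "origin": pop})

    samples = pd.DataFrame(rows)
    gm = GenotypeMatrix(dosage=np.vstack(dosage_rows),
                        loci=ref_freqs.loci.copy(),
                        samples=samples[["id", "group", "tactic", "year"]])
    truth_samples = samples.rename(columns={"id": "sample_id"})[
        ["sample_id", "origin", "tactic", "year"]]
    truth_samples["kin_of"] = None
    loci_truth = (truth.loci.copy() if truth is not None
                  else ref_freqs.loci.assign(tactic_locus=False, dup_artifact=False))
    return gm, TruthTable(samples=truth_samples, loci=loci_truth,
                          pop_freqs=ref_freqs)


def inject_artifacts(gm: GenotypeMatrix, config: SimConfig,
                     truth: TruthTable | None = None
                     ) -> tuple[GenotypeMatrix, TruthTable | None]:
    """Add read-depth structure, merged-paralog loci, and kin duplicates.

    * per-genotype depth ~ NegBin(mean, dispersion); calls below the minimum
      depth become missing; AD fields get Beta(20, 20) allelic balance at
      heterozygotes;
    * ``config.dup_loci`` pairs of loci are merged read-wise (the second of
      each pair is absorbed into the first and dropped), producing excess
      heterozygosity and skewed read ratios at the merged locus;
    * ``config.kin_pairs`` samples are duplicated with 5% of genotypes
      re-drawn, planting near-twin kin pairs.
    """
    if config.dup_loci > gm.n_loci // 2:
        raise ValueError("dup_loci exceeds half the locus count")
    rng = _sub_rng(config.seed, 2)
    mean_d, disp, min_d = config.missing_model

    n, m = gm.dosage.shape
    # NB parameterized by mean/dispersion: n=disp, p=disp/(disp+mean)
    depth = rng.negative_binomial(disp, disp / (disp + mean_d), size=(n, m))
    balance = rng.beta(20, 20, size=(n, m))
    alt_reads = np.where(gm.dosage == 1,
                         rng.binomial(depth, balance),
                         np.where(gm.dosage == 2, depth, 0))
    ref_reads = depth - alt_reads
    ad = np.stack([ref_reads, alt_reads], axis=2)
    dosage = gm.dosage.copy()
    dosage[depth < min_d] = MISSING

    loci = gm.loci.copy()
    dup_flag = np.zeros(m, dtype=bool)
    keep = np.ones(m, dtype=bool)
    if config.dup_loci:
        # merge reasonably polymorphic loci: collapsed paralogs are visible
        # to HDplot only when both collapsed copies carry segregating alleles
        p = gm.alt_freq()
        maf = np.minimum(np.nan_to_num(p, nan=0.0), 1 - np.nan_to_num(p, nan=1.0))
        pool = np.flatnonzero(maf >= 0.15)
        if len(pool) < 2 * config.dup_loci:
            pool = np.argsort(-maf)[:2 * config.dup_loci]
        chosen = rng.choice(pool, size=2 * config.dup_loci, replace=False)
        for a, b in chosen.reshape(-1, 2):
            ad[:, a, :] += ad[:, b, :]
            depth[:, a] += depth[:, b]
            tot = ad[:, a, :].sum(axis=1)
            frac = np.divide(ad[:, a, 1], np.maximum(tot, 1))
            merged = np.select([frac < 0.2, frac > 0.8], [0, 2], default=1)
            dosage[:, a] = np.where(tot >= min_d, merged, MISSING).astype(np.int8)
            dup_flag[a] = True
            keep[b] = False

    samples = gm.samples.copy()
    kin_pairs: list[tuple[str, str]] = []
    if config.kin_pairs:
        src = rng.choice(n, size=config.kin_pairs, replace=False)
        extra_rows, extra_d, extra_dp, extra_ad = [], [], [], []
        for s in src:
            twin = dosage[s].copy()
            redraw = rng.random(m) < config.kin_redraw
            p = gm.alt_freq(gm.groups == samples.iloc[s]["group"])
            twin[redraw] = rng.binomial(2, np.nan_to_num(p[redraw], nan=0.5))
            new_id = samples.iloc[s]["id"] + "_kin"
            row = samples.iloc[s].copy()
            row["id"] = new_id
            extra_rows.append(row)
            extra_d.append(twin)
            extra_dp.append(depth[s])
            extra_ad.append(ad[s])
            kin_pairs.append((samples.iloc[s]["id"], new_id))
        samples = pd.concat([samples, pd.DataFrame(extra_rows)], ignore_index=True)
        dosage = np.vstack([dosage, np.array(extra_d)])
        depth = np.vstack([depth, np.array(extra_dp)])
        ad = np.concatenate([ad, np.array(extra_ad)], axis=0)

    out = GenotypeMatrix(dosage=dosage[:, keep], loci=loci[keep],
                         samples=samples, depth=depth[:, keep],
                         allele_depths=ad[:, keep])
    if truth is not None:
        tloci = truth.loci.copy()
        tloci["dup_artifact"] = dup_flag | tloci.get("dup_artifact", False)
        tloci = tloci[keep].reset_index(drop=True)
        tsamples = truth.samples.copy()
        if kin_pairs:
            add = []
            for orig, new in kin_pairs:
                row = tsamples[tsamples["sample_id"] == orig].iloc[0].copy()
                row["sample_id"] = new
                row["kin_of"] = orig
                add.append(row)
            tsamples = pd.concat([tsamples, pd.DataFrame(add)], ignore_index=True)
        truth = TruthTable(samples=tsamples, loci=tloci,
                           pop_freqs=truth.pop_freqs, kin_pairs=kin_pairs)
    return out, truth


# ---------------------------------------------------------------------------
# distances and output
# ---------------------------------------------------------------------------

def tree_distances(tree: PopNode, scale: float = 1.0) -> pd.DataFrame:
    """Pairwise leaf-to-leaf distances (km) along the tree (patristic path)."""
    paths: dict[str, dict[str, float]] = {}

    def walk(node: PopNode, acc: dict[str, float]):
        acc = dict(acc)
        if node.name != tree.name:
            acc[node.name] = node.km
        if not node.children:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree, {})
    leaves = sorted(paths)
    d = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            shared = set(paths[a]) & set(paths[b])
            dist = (sum(v for k, v in paths[a].items() if k not in shared)
                    + sum(v for k, v in paths[b].items() if k not in shared))
            d.loc[a, b] = d.loc[b, a] = dist * scale
    return d


def write_study(gm: GenotypeMatrix, truth: TruthTable, outdir: str | Path,
                config: SimConfig | None = None) -> dict[str, Path]:
    """Write the simulated study to disk: VCF, popmap, tactic table,
    distance matrix (if a tree is available), and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "popmap": outdir / "popmap.tsv",
        "tactics": outdir / "tactics.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
        "truth_loci": outdir / "truth_loci.tsv",
    }
    write_vcf(gm, paths["vcf"])
    gm.samples[["id", "group"]].to_csv(paths["popmap"], sep="\t",
                                       index=False, header=False)
    tac = gm.samples.copy()
    if "tactic" not in tac:
        tac["tactic"] = None
    if "year" not in tac:
        tac["year"] = None
    tac = tac[["id", "tactic", "year"]].rename(columns={"id": "sample_id"})
    tac["tactic"] = tac["tactic"].fillna("NA")
    tac.to_csv(paths["tactics"], sep="\t", index=False)
    truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    truth.loci.to_csv(paths["truth_loci"], sep="\t", index=False)
    if config is not None and config.pop_tree is not None:
        dist = tree_distances(config.pop_tree, config.distance_scale_km)
        paths["distances"] = outdir / "distances.tsv"
        dist.to_csv(paths["distances"], sep="\t")
    return paths
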