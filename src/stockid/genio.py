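"""Genotype data model, VCF/TSV input and output, and the post-genotyping QC filter cascade.

The central container is :class:`GenotypeMatrix`: a samples x loci matrix of
diploid alt-allele dosages (0, 1, 2, or missing) with locus coordinates and
per-sample metadata (population group, optional life-history tactic and
sampling year).  All quality-control filters operate on and return new
``GenotypeMatrix`` instances and can log their effect into a
:class:`FilterReport` whose counts telescope step to step.

Missing genotypes are encoded as -1 in the integer dosage matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "AlleleFreqTable",
    "FilterParams",
    "FilterStep",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "genotype_depth_filter",
    "locus_filter",
    "sample_missingness_filter",
    "relatedness_yang",
    "relatedness_filter",
    "heterozygosity_filter",
    "hdplot",
    "hdplot_filter",
    "ld_prune",
    "ibm_check",
    "allele_freq_table",
    "filter_cascade",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP genotypes with locus and sample metadata.

    Parameters
    ----------
    dosage
        ``(n_samples, n_loci)`` integer array of alt-allele counts per
        genotype; ``-1`` marks a missing call.
    loci
        DataFrame with columns ``chrom, pos, ref, alt``; rows sorted by
        (chrom, pos) and unique on (chrom, pos).
    samples
        DataFrame with columns ``id, group`` and optional ``tactic, year``;
        ``id`` unique.
    depth
        Optional per-genotype read depth, same shape as ``dosage``.
    allele_depths
        Optional ``(n_samples, n_loci, 2)`` array of (ref, alt) read counts.
    """

    dosage: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame
    depth: np.ndarray | None = None
    allele_depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x loci)")
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample rows for {n} dosage rows")
        if len(self.loci) != m:
            raise ValueError(f"{len(self.loci)} locus rows for {m} dosage columns")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or missing (-1)")
        if self.samples["id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        key = self.loci[["chrom", "pos"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos) loci")
        order = np.lexsort((self.loci["pos"].to_numpy(), self.loci["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(m)):
            raise ValueError("loci must be sorted by (chrom, pos)")
        self.loci = self.loci.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        for name in ("depth", "allele_depths"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                expect = (n, m) if name == "depth" else (n, m, 2)
                if arr.shape != expect:
                    raise ValueError(f"{name} has shape {arr.shape}, expected {expect}")
                setattr(self, name, arr)

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.dosage != MISSING

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["id"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.samples["group"].to_numpy()

    def locus_names(self) -> np.ndarray:
        return (self.loci["chrom"].astype(str) + ":" + self.loci["pos"].astype(str)).to_numpy()

    def sample_missing_fraction(self) -> np.ndarray:
        return 1.0 - self.called.mean(axis=1)

    def take(self, sample_idx: np.ndarray | None = None,
             locus_idx: np.ndarray | None = None) -> "GenotypeMatrix":
        """Subset by positional index or boolean mask along either axis."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if li.dtype == bool:
            li = np.flatnonzero(li)
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(si, li)],
            loci=self.loci.iloc[li],
            samples=self.samples.iloc[si],
            depth=None if self.depth is None else self.depth[np.ix_(si, li)],
            allele_depths=None if self.allele_depths is None
            else self.allele_depths[np.ix_(si, li)],
        )

    def alt_freq(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-locus alt-allele frequency over called genotypes (NaN if none)."""
        d = self.dosage if sample_mask is None else self.dosage[sample_mask]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0)
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)


@dataclass
class AlleleFreqTable:
    """Per-population per-locus alt-allele frequencies with sample-size support."""

    pops: list[str]
    loci: pd.DataFrame                   # chrom, pos, ref, alt
    freqs: np.ndarray                    # (n_pops, n_loci), NaN where uncalled
    n_called: np.ndarray                 # (n_pops, n_loci) diploid counts

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.n_called = np.asarray(self.n_called)
        if self.freqs.shape != (len(self.pops), len(self.loci)):
            raise ValueError("freqs shape does not match pops x loci")
        if self.n_called.shape != self.freqs.shape:
            raise ValueError("n_called shape does not match freqs")

    def pop_index(self, pop: str) -> int:
        return self.pops.index(pop)


def allele_freq_table(gm: GenotypeMatrix, by: str = "group") -> AlleleFreqTable:
    """Compute per-group allele frequencies from a genotype matrix."""
    labels = gm.samples[by].to_numpy()
    pops = sorted(pd.unique(labels))
    freqs = np.empty((len(pops), gm.n_loci))
    n_called = np.empty((len(pops), gm.n_loci), dtype=int)
    for i, p in enumerate(pops):
        mask = labels == p
        d = gm.dosage[mask]
        called = d != MISSING
        n_called[i] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[i] = np.where(n_called[i] > 0,
                                np.where(called, d, 0).sum(axis=0) / (2.0 * n_called[i]),
                                np.nan)
    return AlleleFreqTable(pops=pops, loci=gm.loci.copy(), freqs=freqs, n_called=n_called)


# ---------------------------------------------------------------------------
# filter bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class FilterParams:
    """Thresholds of the QC cascade, in the order the pipeline applies them."""

    min_genotype_depth: int = 3
    max_group_missing_pass1: float = 0.40
    min_rare_allele_samples_pass1: int = 3
    max_group_missing_pass2: float = 0.50
    min_rare_allele_samples_pass2: int = 5
    max_sample_missing_fraction: float = 0.05
    relatedness_threshold: float = 0.9
    het_threshold: float = 0.3
    hdplot_max_h: float = 0.6
    hdplot_max_abs_d: float = 7.0
    ld_r2: float = 0.5
    ld_window_bp: int = 100_000
    maf_ne: float = 0.05

    def __post_init__(self) -> None:
        for name in ("max_group_missing_pass1", "max_group_missing_pass2",
                     "max_sample_missing_fraction", "het_threshold",
                     "ld_r2", "maf_ne", "hdplot_max_h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("min_genotype_depth", "min_rare_allele_samples_pass1",
                     "min_rare_allele_samples_pass2", "ld_window_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FilterStep:
    name: str
    n_samples_in: int
    n_samples_out: int
    n_loci_in: int
    n_loci_out: int
    removed_samples: list[str] = field(default_factory=list)
    removed_loci: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    steps: list[FilterStep] = field(default_factory=list)

    def add(self, step: FilterStep) -> None:
        if self.steps:
            last = self.steps[-1]
            if (step.n_samples_in != last.n_samples_out
                    or step.n_loci_in != last.n_loci_out):
                raise ValueError(
                    f"step '{step.name}' does not telescope from '{last.name}'")
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"step": s.name,
             "samples_in": s.n_samples_in, "samples_out": s.n_samples_out,
             "loci_in": s.n_loci_in, "loci_out": s.n_loci_out,
             "n_samples_removed": len(s.removed_samples),
             "n_loci_removed": len(s.removed_loci)}
            for s in self.steps])

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.to_frame().to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        payload = [
            {"step": s.name,
             "samples": [s.n_samples_in, s.n_samples_out],
             "loci": [s.n_loci_in, s.n_loci_out],
             "removed_samples": list(s.removed_samples),
             "removed_loci": list(s.removed_loci)}
            for s in self.steps]
        prefix.with_suffix(".json").write_text(json.dumps(payload, indent=1))


def _log(report: FilterReport | None, name: str,
         before: GenotypeMatrix, after: GenotypeMatrix) -> None:
    if report is None:
        return
    rem_s = sorted(set(before.sample_ids) - set(after.sample_ids))
    rem_l = sorted(set(before.locus_names()) - set(after.locus_names()))
    report.add(FilterStep(name, before.n_samples, after.n_samples,
                          before.n_loci, after.n_loci, rem_s, rem_l))


# ---------------------------------------------------------------------------
# VCF / TSV I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, popmap: str | Path | pd.DataFrame,
             tactic_table: str | Path | pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read diploid biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    ``popmap`` maps sample id to population group (TSV ``sample_id\\tpopulation``
    or equivalent DataFrame); every VCF sample must appear in it.  An optional
    tactic table (``sample_id, tactic, year``) attaches life-history labels.
    Multiallelic or non-SNP records are rejected.
    """
    from cyvcf2 import VCF

    if not isinstance(popmap, pd.DataFrame):
        popmap = pd.read_csv(popmap, sep="\t", header=None,
                             names=["sample_id", "population"], dtype=str,
                             comment="#")
    pop_of = dict(zip(popmap.iloc[:, 0].astype(str), popmap.iloc[:, 1].astype(str)))

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    absent = [s for s in ids if s not in pop_of]
    if absent:
        raise ValueError(f"samples absent from popmap: {', '.join(absent)}")

    dosages, depths, ads, loci = [], [], [], []
    have_dp = have_ad = True
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise ValueError(
                f"record {var.CHROM}:{var.POS} is not a biallelic SNP")
        # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = var.gt_types
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosages.append(dos.astype(np.int8))
        loci.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        if have_dp:
            try:
                dp = var.format("DP")
            except KeyError:
                dp = None
            if dp is None:
                have_dp = False
            else:
                depths.append(np.where(dp < 0, 0, dp).reshape(-1))
        if have_ad:
            try:
                ad = var.format("AD")
            except KeyError:
                ad = None
            if ad is None or ad.shape[1] != 2:
                have_ad = False
            else:
                ads.append(np.where(ad < 0, 0, ad))
    vcf.close()

    loci_df = pd.DataFrame(loci, columns=["chrom", "pos", "ref", "alt"])
    samples = pd.DataFrame({"id": ids, "group": [pop_of[s] for s in ids]})
    if tactic_table is not None:
        if not isinstance(tactic_table, pd.DataFrame):
            tactic_table = pd.read_csv(tactic_table, sep="\t", dtype=str)
        tt = tactic_table.set_index(tactic_table.columns[0])
        samples["tactic"] = [tt["tactic"].get(s, None) if "tactic" in tt else None
                             for s in ids]
        if "year" in tt:
            samples["year"] = [tt["year"].get(s, None) for s in ids]

    dosage = (np.stack(dosages, axis=1) if dosages
              else np.empty((len(ids), 0), dtype=np.int8))
    depth = np.stack(depths, axis=1) if (have_dp and depths) else None
    allele_depths = np.stack(ads, axis=1) if (have_ad and ads) else None
    return GenotypeMatrix(dosage=dosage, loci=loci_df, samples=samples,
                          depth=depth, allele_depths=allele_depths)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as VCFv4.2 with GT (and DP/AD where present)."""
    fmt_keys = ["GT"]
    if gm.depth is not None:
        fmt_keys.append("DP")
    if gm.allele_depths is not None:
        fmt_keys.append("AD")
    fmt = ":".join(fmt_keys)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stockid\n")
        for chrom in pd.unique(gm.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if "DP" in fmt_keys:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if "AD" in fmt_keys:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j in range(gm.n_loci):
            row = gm.loci.iloc[j]
            if len(str(row.ref)) != 1 or len(str(row.alt)) != 1:
                raise ValueError(
                    f"locus {row.chrom}:{row.pos} is not a biallelic SNP")
            cells = []
            for i in range(gm.n_samples):
                parts = [gt_str[int(gm.dosage[i, j])]]
                if "DP" in fmt_keys:
                    parts.append(str(int(gm.depth[i, j])))
                if "AD" in fmt_keys:
                    parts.append(f"{int(gm.allele_depths[i, j, 0])},"
                                 f"{int(gm.allele_depths[i, j, 1])}")
                cells.append(":".join(parts))
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\t"
                     f"{fmt}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def genotype_depth_filter(gm: GenotypeMatrix, min_depth: int = 3,
                          report: FilterReport | None = None) -> GenotypeMatrix:
    """Set genotypes with read depth below ``min_depth`` to missing."""
    if gm.depth is None:
        raise ValueError("genotype_depth_filter requires a depth field")
    dosage = np.where(gm.depth < min_depth, MISSING, gm.dosage).astype(np.int8)
    out = GenotypeMatrix(dosage=dosage, loci=gm.loci, samples=gm.samples,
                         depth=gm.depth, allele_depths=gm.allele_depths)
    _log(report, f"genotype_depth>={min_depth}", gm, out)
    return out


def locus_filter(gm: GenotypeMatrix, max_group_missing: float = 0.40,
                 min_rare_allele_samples: int = 3,
                 report: FilterReport | None = None) -> GenotypeMatrix:
    """Keep loci with bounded per-group missingness and enough rare-allele carriers.

    A locus survives iff every group's missing fraction is at most
    ``max_group_missing`` and at least ``min_rare_allele_samples`` samples
    carry the globally rarer allele (a carrier is a het or a homozygote for
    that allele).  Both boundaries are inclusive.
    """
    labels = gm.groups
    called = gm.called
    keep = np.ones(gm.n_loci, dtype=bool)
    for g in pd.unique(labels):
        mask = labels == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        miss = 1.0 - called[mask].mean(axis=0)
        keep &= miss <= max_group_missing + 1e-12

    p = gm.alt_freq()
    alt_minor = np.nan_to_num(p, nan=0.0) <= 0.5
    d = gm.dosage
    carriers_alt = ((d == 1) | (d == 2)).sum(axis=0)
    carriers_ref = ((d == 1) | (d == 0)).sum(axis=0)
    carriers = np.where(alt_minor, carriers_alt, carriers_ref)
    # a monomorphic locus has zero carriers of the (absent) minor allele
    mono = np.isnan(p) | (p == 0.0) | (p == 1.0)
    carriers = np.where(mono, 0, carriers)
    keep &= carriers >= min_rare_allele_samples

    out = gm.take(locus_idx=keep)
    _log(report, f"locus_miss<={max_group_missing}_mac>={min_rare_allele_samples}",
         gm, out)
    return out


def sample_missingness_filter(gm: GenotypeMatrix, max_fraction: float = 0.05,
                              report: FilterReport | None = None) -> GenotypeMatrix:
    """Remove samples whose missing-data fraction strictly exceeds ``max_fraction``."""
    keep = gm.sample_missing_fraction() <= max_fraction + 1e-12
    out = gm.take(sample_idx=keep)
    _log(report, f"sample_missing<={max_fraction}", gm, out)
    return out


def relatedness_yang(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise Yang et al. relatedness statistic A_jk.

    A_jk = mean over polymorphic loci (called in both samples) of
    ``(x_j - 2p)(x_k - 2p) / (2p(1-p))`` with ``p`` the overall alt
    frequency.  Self-pairs on the diagonal are left as NaN.  Duplicated
    genotypes give values near ``1 + F`` (>= 1 for non-inbred samples).
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    p = gm.alt_freq()
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic loci for relatedness")
    d = gm.dosage[:, poly].astype(float)
    pp = p[poly]
    called = d != MISSING
    denom = 2.0 * pp * (1.0 - pp)
    z = np.where(called, (d - 2.0 * pp) / np.sqrt(denom), 0.0)
    num = z @ z.T
    cnt = called.astype(float) @ called.astype(float).T
    if (np.triu(cnt, 1)[np.triu_indices(gm.n_samples, 1)] == 0).any():
        raise ValueError("a sample pair shares no called polymorphic loci")
    with np.errstate(invalid="ignore", divide="ignore"):
        a = num / cnt
    np.fill_diagonal(a, np.nan)
    ids = gm.sample_ids
    return pd.DataFrame(a, index=ids, columns=ids)


def relatedness_filter(gm: GenotypeMatrix, threshold: float = 0.9,
                       report: FilterReport | None = None
                       ) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Drop one member of each pair whose relatedness exceeds ``threshold``.

    The member with more missing data is dropped; ties break on sample id so
    the outcome is deterministic.  Returns the filtered matrix and the list
    of flagged pairs.
    """
    a = relatedness_yang(gm).to_numpy()
    miss = gm.sample_missing_fraction()
    ids = gm.sample_ids
    flagged: list[tuple[str, str]] = []
    drop: set[int] = set()
    for i, j in zip(*np.where(np.triu(a, 1) >= threshold)):
        flagged.append((ids[i], ids[j]))
        if i in drop or j in drop:
            continue
        if miss[i] > miss[j] or (miss[i] == miss[j] and ids[i] > ids[j]):
            drop.add(i)
        else:
            drop.add(j)
    keep = np.array([i not in drop for i in range(gm.n_samples)])
    out = gm.take(sample_idx=keep)
    _log(report, f"relatedness<{threshold}", gm, out)
    return out, flagged


def heterozygosity_filter(gm: GenotypeMatrix, het_threshold: float = 0.3,
                          report: FilterReport | None = None) -> GenotypeMatrix:
    """Remove samples whose observed heterozygosity strictly exceeds the threshold."""
    called = gm.called
    ho = (gm.dosage == 1).sum(axis=1) / np.maximum(called.sum(axis=1), 1)
    out = gm.take(sample_idx=ho <= het_threshold)
    _log(report, f"heterozygosity<={het_threshold}", gm, out)
    return out


def hdplot(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus paralog diagnostics: heterozygote fraction H and read-ratio deviation D.

    H is the fraction of called samples that are heterozygous.  D sums reads
    over heterozygous calls only: ``D = (sum ref - sum alt) / sqrt(sum total)``,
    a z-like score that is near 0 for balanced alleles at true heterozygotes
    and large for collapsed paralogs.  Loci with no heterozygotes get D = 0.
    """
    if gm.allele_depths is None:
        raise ValueError("hdplot requires allele depths (AD)")
    called = gm.called
    het = gm.dosage == 1
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n_called > 0, het.sum(axis=0) / n_called, 0.0)
    ref = np.where(het, gm.allele_depths[:, :, 0], 0).sum(axis=0)
    alt = np.where(het, gm.allele_depths[:, :, 1], 0).sum(axis=0)
    tot = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, (ref - alt) / np.sqrt(np.maximum(tot, 1)), 0.0)
    return pd.DataFrame({"chrom": gm.loci["chrom"], "pos": gm.loci["pos"],
                         "H": h, "D": d})


def hdplot_filter(gm: GenotypeMatrix, max_h: float = 0.6, max_abs_d: float = 7.0,
                  report: FilterReport | None = None) -> GenotypeMatrix:
    """Keep only canonical ('singleton') loci: H <= max_h and |D| <= max_abs_d."""
    hd = hdplot(gm)
    keep = (hd["H"].to_numpy() <= max_h) & (np.abs(hd["D"].to_numpy()) <= max_abs_d)
    out = gm.take(locus_idx=keep)
    _log(report, f"hdplot_H<={max_h}_|D|<={max_abs_d}", gm, out)
    return out


def ld_prune(gm: GenotypeMatrix, r2: float = 0.5, window_bp: int = 100_000,
             report: FilterReport | None = None) -> GenotypeMatrix:
    """Forward-scan LD pruning: keep the first SNP of each linked cluster.

    Loci are scanned in (chrom, pos) order; a locus is dropped when its
    squared dosage correlation with any *retained* locus at most
    ``window_bp`` upstream on the same chromosome exceeds ``r2``.
    Correlations use pairwise-complete genotypes.
    """
    keep = np.ones(gm.n_loci, dtype=bool)
    d = gm.dosage.astype(float)
    d[gm.dosage == MISSING] = np.nan
    chroms = gm.loci["chrom"].to_numpy()
    pos = gm.loci["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        retained: list[int] = []
        for j in idx:
            drop = False
            for k in reversed(retained):
                if pos[j] - pos[k] > window_bp:
                    break
                both = ~(np.isnan(d[:, j]) | np.isnan(d[:, k]))
                if both.sum() < 2:
                    continue
                x, y = d[both, j], d[both, k]
                if x.std() == 0 or y.std() == 0:
                    continue
                if np.corrcoef(x, y)[0, 1] ** 2 > r2:
                    drop = True
                    break
            if drop:
                keep[j] = False
            else:
                retained.append(j)
    out = gm.take(locus_idx=keep)
    _log(report, f"ld_prune_r2<={r2}_win{window_bp}", gm, out)
    return out


def ibm_check(gm: GenotypeMatrix, seed: int = 0) -> dict:
    """Identity-by-missingness diagnostic.

    PCA of the binary missingness-indicator matrix followed by 2-means on
    the first two axes; the silhouette score quantifies whether missing data
    forms clusters (batch effects).  Values above ~0.5 suggest structure in
    missingness.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    miss = (~gm.called).astype(float)
    if miss.sum() == 0:
        return {"silhouette": np.nan, "scores": None, "message": "no variation"}
    centered = miss - miss.mean(axis=0)
    if not np.any(centered.std(axis=0) > 0):
        return {"silhouette": np.nan, "scores": None, "message": "no variation"}
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :2] * s[:2]
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(scores)
    if len(np.unique(km.labels_)) < 2:
        return {"silhouette": np.nan, "scores": scores, "message": "degenerate"}
    sil = silhouette_score(scores, km.labels_)
    return {"silhouette": float(sil), "scores": scores, "labels": km.labels_,
            "message": "ok"}


def filter_cascade(gm: GenotypeMatrix, params: FilterParams | None = None
                   ) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full QC cascade in study order and return the filter report.

    Order: genotype depth; locus pass 1 (40% group missingness, >=3 rare-allele
    carriers); sample missingness; locus pass 2 (50%, >=5); relatedness;
    heterozygosity; locus pass 2 re-applied; HDplot paralog removal (if AD
    present); LD pruning.
    """
    params = params or FilterParams()
    report = FilterReport()
    gm = genotype_depth_filter(gm, params.min_genotype_depth, report)
    gm = locus_filter(gm, params.max_group_missing_pass1,
                      params.min_rare_allele_samples_pass1, report)
    gm = sample_missingness_filter(gm, params.max_sample_missing_fraction, report)
    gm = locus_filter(gm, params.max_group_missing_pass2,
                      params.min_rare_allele_samples_pass2, report)
    gm, _ = relatedness_filter(gm, params.relatedness_threshold, report)
    gm = heterozygosity_filter(gm, params.het_threshold, report)
    gm = locus_filter(gm, params.max_group_missing_pass2,
                      params.min_rare_allele_samples_pass2, report)
    if gm.allele_depths is not None:
        gm = hdplot_filter(gm, params.hdplot_max_h, params.hdplot_max_abs_d, report)
    gm = ld_prune(gm, params.ld_r2, params.ld_window_bp, report)
    return gm, report
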