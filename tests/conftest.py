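import numpy as np
import pandas as pd
import pytest

from stockid import genio, simdata
from stockid.simdata import PopNode, SimConfig, YearDesign


def make_gm(dosage, chrom=None, pos=None, groups=None, ids=None,
            depth=None, allele_depths=None, tactic=None, year=None):
    """Build a GenotypeMatrix from plain lists with sensible defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    chrom = ["chr1"] * m if chrom is None else list(chrom)
    pos = list(range(1, m + 1)) if pos is None else list(pos)
    loci = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "C"})
    samples = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)] if ids is None else list(ids),
        "group": ["g"] * n if groups is None else list(groups),
    })
    if tactic is not None:
        samples["tactic"] = tactic
    if year is not None:
        samples["year"] = year
    return genio.GenotypeMatrix(
        dosage=dosage, loci=loci, samples=samples,
        depth=None if depth is None else np.asarray(depth),
        allele_depths=None if allele_depths is None else np.asarray(allele_depths))


def two_pop_config(seed=0, f=0.10, n_loci=2000, n_per_pop=50, n_chrom=4):
    tree = PopNode("R", children=[PopNode("A", f=f, km=100.0),
                                  PopNode("B", f=f, km=100.0)])
    return SimConfig(seed=seed, n_loci=n_loci,
                     chrom_layout=[(f"c{i}", 5_000_000) for i in range(n_chrom)],
                     pop_tree=tree, sample_sizes={"A": n_per_pop, "B": n_per_pop},
                     tactic_loci=(0, 0.0))


def three_pop_mixture_config(seed=0, f=0.08, n_loci=1000, n_mix=300,
                             props=(0.6, 0.3, 0.1)):
    tree = PopNode("R", children=[PopNode(n, f=f, km=100.0)
                                  for n in ("A", "B", "C")])
    origin = dict(zip(("A", "B", "C"), props))
    return SimConfig(seed=seed, n_loci=n_loci,
                     chrom_layout=[(f"c{i}", 2_000_000) for i in range(5)],
                     pop_tree=tree,
                     sample_sizes={"A": 50, "B": 50, "C": 50},
                     mixture_design=[YearDesign("y1", n_mix, origin, {})],
                     tactic_loci=(0, 0.0))


def tactic_scan_config(seed=0, n_loci=3000, delta=0.25, n_tactic_loci=20):
    """Two near-panmictic rivers with tactic-labeled fish and a planted
    polygenic signal, shaped like the within-drainage tactic contrast."""
    tree = PopNode("R", children=[PopNode("GUEDEL", f=0.004, km=10, children=[
        PopNode("GUE", f=0.002, km=1), PopNode("DEL", f=0.002, km=1)])])
    yd = YearDesign("y", 10, {"GUE": 0.5, "DEL": 0.5},
                    {p: {"estuarine": 0.6, "marine": 0.4}
                     for p in ("GUE", "DEL")})
    return SimConfig(seed=seed, n_loci=n_loci,
                     chrom_layout=[(f"c{i:02d}", 5_000_000) for i in range(10)],
                     pop_tree=tree, sample_sizes={"GUE": 99, "DEL": 171},
                     mixture_design=[yd], tactic_loci=(n_tactic_loci, delta))


def wright_fisher_gm(seed, n=50, n_loci=400, n_chrom=8, generations=20):
    """A finite population after some generations of random mating with
    free recombination: carries genuine drift LD for the Ne estimator."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.8, n_loci)
    h0 = rng.random((n, n_loci)) < p
    h1 = rng.random((n, n_loci)) < p
    for _ in range(generations):
        parents = rng.integers(0, n, size=2 * n)
        pick = rng.random((2 * n, n_loci)) < 0.5
        gametes = np.where(pick, h0[parents], h1[parents])
        h0, h1 = gametes[:n], gametes[n:]
    dosage = (h0.astype(int) + h1.astype(int)).astype(np.int8)
    chrom = np.repeat([f"c{i}" for i in range(n_chrom)], n_loci // n_chrom)
    pos = np.tile(np.arange(1, n_loci // n_chrom + 1) * 1000, n_chrom)
    return make_gm(dosage, chrom=chrom, pos=pos,
                   groups=["X"] * n, ids=[f"s{i}" for i in range(n)])


@pytest.fixture(scope="session")
def study_sim():
    """One shared medium-scale study simulation (8 populations, artifacts)."""
    cfg = simdata.study_config(seed=11, n_loci=1500, n_chrom=8)
    ref, truth = simdata.simulate_reference(cfg)
    mix, mtruth = simdata.simulate_mixture(cfg, truth.pop_freqs, truth)
    art, art_truth = simdata.inject_artifacts(ref, cfg, truth)
    return {"cfg": cfg, "ref": ref, "truth": truth, "mix": mix,
            "mix_truth": mtruth, "art": art, "art_truth": art_truth}
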