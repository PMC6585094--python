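"""Generate the synthetic study dataset.

Creates a paternal half-sib population (100 AI sires x 50 progeny = 5000
recorded animals) spread over 200 contemporary groups whose effects span a
realistic post-weaning-gain range, genotypes the population at 2000 SNPs on
10 chromosomes, and plants polygenic QTL plus one large segment-2-slope QTL
so the association stage has a known target.  Writes the data tables and
the truth tables under results/data/.
"""

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from reactnorm.simdata import SimConfig, simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main():
    cfg = SimConfig(
        n_qtl_per_coefficient=50,
        qtl_var_fraction=0.3,
        planted_qtl=("b1s2", 0.10),
        seed=20240901,
    )
    sim = simulate(cfg)
    sim.write(OUT)
    n_rec = len(sim.phenotypes)
    print(f"pedigree: {len(sim.pedigree)} animals ({n_rec} recorded)")
    print(f"genotypes: {sim.genotypes.shape[1]} SNPs on "
          f"{sim.snp_map['chr'].nunique()} chromosomes")
    print(f"contemporary groups: {sim.true_cg.shape[0]}, "
          f"effects {sim.true_cg['effect'].min():.1f}-{sim.true_cg['effect'].max():.1f} kg")
    planted = sim.true_qtl[
        (sim.true_qtl["b1dev"] != 0)
        & (sim.true_qtl["b0"] == 0)
        & (sim.true_qtl["b1"] == 0)
    ]
    print(f"planted segment-2 QTL: {planted.index.tolist()}")
    print(f"wrote tables to {OUT}/")


if __name__ == "__main__":
    main()
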