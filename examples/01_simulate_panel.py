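"""Build a small synthetic inbred-strain panel with two planted metabolite
QTLs and inspect its shape.

The generator emulates an HMDP-style design: ~100 inbred strains with
block-structured genotypes and discrete strain families (population
structure), metabolites in the eight standard classes measured over six
run-days with replicate mice for some strains.
"""

import metaboqtl as mq

cfg = mq.SimulationConfig(
    n_strains=80,
    n_snps=500,
    n_metabolites=20,
    planted_qtls=[(0, 120, 0.5), (1, 400, 0.7)],  # (metabolite, SNP, PVE)
    replicate_strains=[(0, 5)],                    # one strain with 5 mice
    seed=11,
)
G = mq.simulate_genotypes(cfg)
met, truth = mq.simulate_metabolome(G, cfg)

print(f"genotypes: {G.n_strains} strains x {G.n_snps} SNPs "
      f"(MAF range {G.maf.min():.2f}-{G.maf.max():.2f})")
print(f"metabolome: {met.n_samples} samples x {met.n_variables} metabolites, "
      f"{len(set(met.runday_of_sample))} run-days")
print("planted ground truth (metabolite, causal SNP, realized PVE):")
for m, s, pve in truth.qtl_map:
    print(f"  {m}  {s}  {pve:.2f}")
print(f"null metabolites (no planted signal): {len(truth.null_set)}")
# The realized PVE is the causal SNP's share of that metabolite's variance
# actually obtained in this finite draw; downstream scans should find peaks
# at these SNPs and nowhere else.
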