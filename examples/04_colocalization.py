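"""Candidate-gene prioritization by local-eQTL co-localization: a
metabolite QTL and a transcript eQTL planted on the same SNP identify the
gene (the glycerol-3-phosphate / Gpd2 style of evidence)."""

from metaboqtl import benchmarks

demo = benchmarks.colocalization_demo(seed=14)
print(f"planted gene:      {demo['planted_gene']}")
print(f"candidate genes at the metabolite locus: {demo['candidates']}")
print(f"sole candidate recovered: {demo['is_sole_candidate']}")
# A transcript whose expression maps locally (peak SNP within 2 Mb of the
# gene) and whose eQTL peak falls within 1 Mb of the metabolite's peak SNP
# is a mechanistic candidate for that metabolite locus.
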