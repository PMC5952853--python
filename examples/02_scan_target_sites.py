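"""Scan a 3'UTR for canonical miRNA seed-match sites and classify them.

The three canonical site types are built from the miRNA seed (nucleotides
2-8): 7mer-m8 (reverse complement of nt 2-8), 8mer-1a (7mer-m8 plus an A),
and 7mer-1a (reverse complement of nt 2-7 plus an A).  The scanner reports
each site once with its most specific type.
"""

from mirdecay.target_sites import (
    MiRNA,
    classify_apa,
    classify_seed_group,
    scan_sites,
    seed_site_strings,
)

let7 = MiRNA("let-7", "UGAGGUAGUAGGUUGUAUAGUU", expression_rank=1)
print(f"miRNA: {let7.name}  seed(2-8): {let7.seed2_8}")
for site_type, s in seed_site_strings(let7).items():
    print(f"  {site_type:8s} -> {s}")

# a toy 3'UTR: an upstream poly(A) hexamer, then an 8mer site, then a 7mer
utr3 = ("GCGCGC" + "AATAAA" + "GCGCGCGCGCGCGCGCGCGCGCGCGC"
        + "CTACCTCA" + "GCGCGCGCGC" + "CTACCTC" + "GCGC")

sites = scan_sites(utr3, [let7], transcript_id="txDemo", region="UTR3")
print(f"\nsites found in the demo 3'UTR ({len(utr3)} nt):")
for s in sites:
    print(f"  [{s.start:3d}, {s.end:3d})  {s.site_type:8s}  "
          f"{utr3[s.start:s.end]}")

print(f"\nseed group:          {classify_seed_group(sites)}")
print(f"APA status (site 1): {classify_apa(utr3, sites[0])}")
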