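"""Adenylation and degradation ratios from species counts.

With 20 canonical-length reads, 40 templated-extension (+C, the PAPD5
substrate) reads and 10 mono-adenylated (+CA) reads, the adenylation
ratio is 10/40 = 0.25 and the degradation ratio 20/40 = 0.5.  The ratios
are count-scale free, so cpm normalisation does not change them.
"""

from isotail import IsomirKey, tailing_ratios
from isotail.quantify import IsomirProfile

profile = IsomirProfile("demo", {
    IsomirKey("mir-21", "miR-21-5p", 0, 0, ""): 20,    # 22-mer analogue
    IsomirKey("mir-21", "miR-21-5p", 0, 1, ""): 40,    # 23-mer +C
    IsomirKey("mir-21", "miR-21-5p", 0, 1, "A"): 10,   # 24-mer +CA
})

res = tailing_ratios(profile, "mir-21", "miR-21-5p")
print(f"substrate (+C)   count: {res.substrate_count:.0f}")
print(f"tailed   (+CA)   count: {res.tailed_count:.0f}")
print(f"trimmed (canon.) count: {res.trimmed_count:.0f}")
print(f"adenylation ratio = {res.adenylation_ratio}   (tailed / substrate)")
print(f"degradation ratio = {res.degradation_ratio}    (trimmed / substrate)")
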