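"""Forward-backward GEM crosswalk of the ICD-9-CM AMI seed codes.

Starting from the 410.x0/410.x1 families, forward-map to ICD-10-CM and
backward-map to ICD-9-CM over the packaged toy GEM tables.  Codes that
the round trip surfaces beyond the seed are the candidates a clinician
would review for inclusion.
"""

from amiclaims import forward_backward, load_ami_codelist
from amiclaims.resources import load_toy_gems

codelist = load_ami_codelist()
forward_gem, backward_gem = load_toy_gems()

universe = {e.source for e in forward_gem.entries}
seed = codelist.expand(universe, "icd9cm")
report = forward_backward(seed, forward_gem, backward_gem, iterations=2)

print(f"seed (ICD-9-CM):       {sorted(report.seed_codes)}")
print(f"forward (ICD-10-CM):   {sorted(report.forward_set)}")
print(f"backward (ICD-9-CM):   {sorted(report.backward_set)}")
print(f"newly discovered:      {sorted(report.newly_discovered)}")
# The forward set covers the I21/I22 families; newly discovered codes
# (e.g. a subsequent-episode 410.x2 code) are flagged for human review,
# not automatically added to the algorithm.
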