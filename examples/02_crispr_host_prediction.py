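"""Predict a virus's host from CRISPR spacer-protospacer matches.

Plants a CRISPR array in a host genome whose spacers copy protospacers
from a viral genome, then re-detects the array, applies the published
filters (spacer/repeat ratio 0.6-2.5, >= 3 spacers), and matches spacers
back to the virus at >= 95% identity / >= 95% coverage / <= 1 SNP.
"""

import numpy as np

from lysismine import detect_arrays, filter_arrays, host_range, match_spacers
from lysismine.crispr import host_assignments
from lysismine.records import SeqRecord
from lysismine.synth import plant_crispr_link

rng = np.random.default_rng(0)
host = SeqRecord(id="host_A", residues="".join(rng.choice(list("ACGT"), 20_000)),
                 alphabet="nt", source="bacterial")
virus = SeqRecord(id="phage_X", residues="".join(rng.choice(list("ACGT"), 30_000)),
                  alphabet="nt", source="viral")

planted_host, spacers, links = plant_crispr_link(host, virus, n_spacers=4, seed=2)
arrays = filter_arrays(detect_arrays(planted_host))
print(f"arrays detected after filtering: {len(arrays)}")
arr = arrays[0]
print(f"repeat length {len(arr.repeat)} nt, {arr.n_spacers} spacers, "
      f"mean spacer {arr.mean_spacer_length:.1f} nt")

detected = {f"{arr.genome_id}_sp{k}": s for k, (s, _, _) in enumerate(arr.spacers)}
matches = match_spacers(detected, [virus])
print(f"accepted spacer-protospacer matches: {len(matches)}")
assignments = host_assignments(matches, {sid: "Escherichia coli" for sid in detected})
print("host range per virus:", host_range(assignments))
# 4 accepted matches to one host species give phage_X a host range of 1:
# every spacer in the array points back at its protospacer in the virus.
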