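"""GO biological-process enrichment of a candidate gene set.

Annotations are closed over the is_a hierarchy, terms below the
genome-scale floor (50 genes) are discarded, and each term gets a
one-sided Fisher exact p-value for over-representation in the query.
"""

import numpy as np

from estsplice import enrich
from estsplice.enrichment import OntologyGraph, enrichment_table

bp = "biological_process"
parents = {"GO:ROOT": frozenset(),
           "GO:PROLIF": frozenset({"GO:ROOT"}),
           "GO:METAB": frozenset({"GO:ROOT"}),
           "GO:RARE": frozenset({"GO:METAB"})}
names = {"GO:ROOT": "biological process", "GO:PROLIF": "cell proliferation",
         "GO:METAB": "metabolic process", "GO:RARE": "rare pathway"}
ontology = OntologyGraph(parents, names, {t: bp for t in parents})

rng = np.random.default_rng(7)
universe = [f"g{i:03d}" for i in range(400)]
annotations = {}
for i, g in enumerate(universe):
    terms = {"GO:METAB"} if rng.random() < 0.6 else {"GO:ROOT"}
    if i < 60 and rng.random() < 0.8:      # proliferation: enriched in
        terms.add("GO:PROLIF")             # the first 60 genes...
    elif rng.random() < 0.1:               # ...rare elsewhere
        terms.add("GO:PROLIF")
    if rng.random() < 0.05:                # below the 50-gene floor
        terms.add("GO:RARE")
    annotations[g] = terms

query = universe[:60]  # e.g. genes over-expressed in tumors
results = enrich(query, universe, annotations, ontology, p_cut=1.0)
print(enrichment_table(results).to_string(index=False))
print("\n-> 'cell proliferation' is over-represented in the query "
      "(small p); 'rare pathway' is absent: < 50 genes genome-wide")
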