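"""Link free-text diagnoses to SNOMED CT concepts.

Writes the miniature RF2-style description table, then attributes two
diagnosis strings: an exact-term query and a query that requires the
keyword-filter + cosine-rerank path.  Prints the attribution records with
conceptId, matched term and similarity score.
"""

import json
import tempfile
from pathlib import Path

import phqscreen as pq

embedder = pq.get_embedder("reference")
with tempfile.TemporaryDirectory() as tmp:
    table = pq.load_snomed(pq.generate_snomed_fixture(Path(tmp) / "snomed.tsv"))

for diagnosis in ("Depressed mood (finding)", "moderate depression", "qqq"):
    result = pq.attribute(diagnosis, table, embedder)
    print(f"{diagnosis!r} ->", json.dumps(result.to_record()))
# An exact term scores similarity 1.0; "moderate depression" reranks to the
# closest clinical concept; an unmatchable string yields a NoMatch record.
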