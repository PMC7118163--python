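"""Whole pipeline through files, as the CLI drives it.

Simulates a cohort, writes the annotated VCF / reference TSV / metadata,
then runs the single-command discovery driver and prints the outputs it
declared in its manifest. Equivalent shell usage:

    lofburden simulate --seed 11 --n-cases 200 --n-genes 100 --out sim/
    lofburden run --vcf sim/cohort.vcf --reference sim/reference_counts.tsv \
        --metadata sim/metadata.tsv --out results/
"""

import json
import tempfile
from pathlib import Path

from lofburden.config import DiscoveryConfig
from lofburden.pipeline import run_discovery
from lofburden.synthetic_cohort import SimulationSpec, simulate_cohort

work = Path(tempfile.mkdtemp())
spec = SimulationSpec(seed=11, n_cases=200, n_genes=100,
                      planted_genes=(("G0042", 12.0),))
files = simulate_cohort(spec).write(work / "sim")
outputs = run_discovery(DiscoveryConfig(), files["vcf"], files["reference"],
                        work / "results", metadata=files["metadata"], seed=11)

print("pipeline outputs:")
for name, path in sorted(outputs.items()):
    print(f"  {name:<22s} {path.name}")
tests = json.loads(outputs["cohort_tests"].read_text())
print("\ncohort-level summary:", json.dumps(tests, indent=2))
# ranked_genes.tsv holds the full Fisher ranking; candidate_genes.tsv the
# prioritised subset (>= 3 carriers, p <= BH threshold, >= 3-fold enriched).
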