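"""One-shot end-to-end run through the orchestrator.

Executes every stage (simulate -> QC -> normalize -> map -> meta/mega ->
conditional -> enrichment -> GWAS overlap) in one call and prints the
machine-readable summary, demonstrating that the stage outputs written by
scripts 01-07 are reproduced by the single entry point.
"""

import json

from liverqtl.pipeline import run_pipeline

from common import pipeline_config

summary = run_pipeline(pipeline_config())
print(json.dumps(summary, indent=2, default=float))
print("\nrun directory:", pipeline_config().output_dir)
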