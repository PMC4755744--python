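"""End-to-end replica run: simulate a cohort, run every analysis stage.

Uses the replica generator (rotating stimulus code, transient shared
template code, late signed-distance code) and prints the stage summaries
from the manifest.
"""

import json
import warnings

from popdecode import pipeline

warnings.simplefilter("ignore")

cfg = pipeline.paper_replica_config(seed=0, n_subjects=6, n_perm=300,
                                    crosstime_step_ms=36.0,
                                    out_dir="scratch/pipeline_run")
manifest = pipeline.run_pipeline(cfg)
print(json.dumps(manifest["stages"], indent=1, default=str))
print("\nExpected qualitative pattern: template decoding onset precedes "
      "the stimulus onset, angular-distance decoding starts late, the "
      "stimulus matrix shows dynamic (diagonal-dominant) coding, and the "
      "sign-axis divergence emerges after ~350 ms.")
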