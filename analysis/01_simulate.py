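"""Generate the two synthetic microcosm datasets used by the analyses.

Writes under results/simulated/:
  default/   -- factor-hierarchy community (matrix > time > contamination)
                plus concentration series for MFN/MET/TER
  benchmark/ -- planted-interaction community with ground-truth categories
"""

import sys
from pathlib import Path

from mixshift import synth

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "simulated"

for name, factory in (("default", synth.default_spec),
                      ("benchmark", synth.interaction_benchmark_spec)):
    spec = factory(SEED)
    paths = synth.write_outputs(spec, OUT / name)
    table_path = paths["counts"]
    print(f"[{name}] seed={SEED} n_taxa={spec.n_taxa} "
          f"depth~{spec.depth_mean} -> {Path(table_path).parent}")
print("done: counts/taxonomy/metadata/concentrations/truth TSVs written")
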