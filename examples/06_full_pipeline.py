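"""Run the whole pipeline and list the report bundle it writes.

One call chains simulate -> derive -> summarize -> ROC -> screening rules
-> logistic models and writes every table as CSV/JSON with a provenance
header; the same config and seed always give byte-identical outputs.
"""

import pathlib

import apdscreen as a

out = pathlib.Path("scratch_bundle")
a.run_pipeline(a.RunConfig(out_dir=str(out), seed=1,
                           cohort_config=a.default_config()))

for path in sorted(out.iterdir()):
    print(f"{path.name:24s} {path.stat().st_size:6d} bytes")
print("\nrun log:")
print((out / "run.log").read_text())
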