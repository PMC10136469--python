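"""End-to-end run: simulate -> preprocess -> behavior -> IBS -> GCA ->
classify, with stage caching and a manifest.

Reduced sizes keep this example to about a minute; the acceptance
script (scripts/acceptance.py) runs the full 17 + 18 cohort.
"""

import logging

import hyperdyad as hd

logging.basicConfig(level=logging.INFO, format="%(message)s")

config = hd.AnalysisConfig(perm_iterations=200, knn_null_iterations=500)
manifest = hd.run_all(config, "scratch/example_run",
                      n_couples=6, n_controls=6, seed=7)
print(f"\nstages completed: {', '.join(manifest['stages'])}")
print("\n" + open("scratch/example_run/summary.md").read())
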