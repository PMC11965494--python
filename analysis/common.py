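"""Shared configuration for the numbered analysis scripts.

Every script reads its inputs from (and writes its outputs to) RESULTS, so
the stages can be run in sequence:

    python analysis/01_generate_inputs.py
    python analysis/02_predict_proteins.py
    ...

A single SEED drives all randomness; re-running any stage reproduces its
outputs byte-for-byte.
"""

from pathlib import Path

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
RESULTS.mkdir(parents=True, exist_ok=True)

FIT_OPTS = dict(sim_opts=dict(grid_h=0.5, rtol=1e-6, atol=1e-8,
                              check_entrainment=False))
LD_WINDOW = (0.0, 24.0)
LL_WINDOW = (48.0, 72.0)
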