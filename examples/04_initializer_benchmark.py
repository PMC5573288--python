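"""The full initializer x solver comparison grid on one phantom.

Reproduces the shape of the clinical comparison at phantom scale: rows are
initializers (SPA, NNDSVD, FCM, random), columns are solvers, entries are
whole-tumor Dice and iterations to convergence.  The non-deterministic
initializers (random, FCM) use best-of-n restarts; n is reduced here to
keep the demo quick.
"""

import tempfile
from pathlib import Path

import spanmf as sp

with tempfile.TemporaryDirectory() as tmp:
    cfg = sp.PipelineConfig(
        rank=4,
        initializers=("spa", "nndsvd", "fcm", "random"),
        solvers=("ahals", "pg"),
        solver_config=sp.SolverConfig(n_restarts=5),
        phantom=sp.PhantomConfig(grid_shape=(32, 32), snr_db=30.0, seed=4),
        out_dir=tmp,
    )
    manifest = sp.run_pipeline(cfg)
    print("whole-tumor Dice grid:")
    print((Path(tmp) / "dice_whole.tsv").read_text())
    print("iterations to convergence:")
    print((Path(tmp) / "iterations.tsv").read_text())
print("All initializers land within a few Dice points of each other; SPA "
      "gets there deterministically and without restarts.")
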