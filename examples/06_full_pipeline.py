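"""Run the whole pipeline from one configuration file.

Chains simulate -> preprocess -> screen -> fit -> predict -> project ->
report into an output directory and prints the run summary.  The same run
is available from the shell as `socgwr run-all --config examples/config.yaml`.
"""

import logging
import tempfile
from pathlib import Path

from socgwr.config import read_config
from socgwr.pipeline import run_all

logging.basicConfig(level=logging.WARNING)

cfg = read_config(Path(__file__).parent / "config.yaml")
with tempfile.TemporaryDirectory() as td:
    cfg.outdir = td
    bundle = run_all(cfg)
    print("report sections:", ", ".join(sorted(bundle)))
    print()
    print((Path(td) / "report" / "summary.txt").read_text())
print("-> every artifact (tables, rasters, manifests) was written under the "
      "run directory; rerunning the same config reproduces it byte for byte")
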