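"""Round-trip landmark files through the supported dialects.

Writes one configuration as plain CSV, Slicer fcsv and TPS, reads each
back and prints the worst coordinate discrepancy (well below 1e-9) and
the LPS -> RAS conversion applied to Slicer files.
"""

import numpy as np

from ontotraj import LandmarkConfiguration, read_landmarks, write_landmarks

rng = np.random.default_rng(1)
config = LandmarkConfiguration(
    rng.normal(size=(6, 3)) * 20, [f"lm{i}" for i in range(6)]
)

import tempfile
from pathlib import Path

with tempfile.TemporaryDirectory() as tmp:
    for dialect in ("csv", "fcsv", "tps"):
        path = Path(tmp) / f"specimen.{dialect}"
        write_landmarks(config, path)
        back = read_landmarks(path)
        err = np.abs(back.coords - config.coords).max()
        print(f"{dialect:5s} round trip: max coordinate error {err:.2e}")

    # Slicer files declaring LPS coordinates are converted to RAS
    lps = Path(tmp) / "lps.fcsv"
    lps.write_text(
        "# Markups fiducial file version = 4.11\n"
        "# CoordinateSystem = LPS\n"
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n"
        "n1,1,2,3,0,0,0,1,1,1,0,A,,\n"
    )
    cfg = read_landmarks(lps)
    print(f"\nLPS (1, 2, 3) read into the internal RAS frame: {cfg.coords[0]}")
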