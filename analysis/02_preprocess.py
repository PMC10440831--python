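#!/usr/bin/env python
"""Preprocess the raw phantom cube and report per-stage statistics.

Applies the six-stage chain (rubber-band baseline, PCA noise reduction,
EMSC scattering correction, amide-I quality gate, paraffin/fingerprint
truncation, vector normalisation) and writes the stage report plus the
class-mean spectra of the preprocessed cube.

Requires analysis/01_generate_phantom.py to have run (reads scratch/run/).
Writes: results/preprocess_stages.csv, results/class_mean_spectra.csv.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ftirfuse import cubeio, phantom, preprocess  # noqa: E402

SEED = 1
HERE = os.path.dirname(os.path.abspath(__file__))
RESULTS = os.path.join(HERE, "..", "results")
SCRATCH = os.path.join(HERE, "..", "scratch", "run")


def main() -> None:
    cube = cubeio.read_cube(os.path.join(SCRATCH, "cube_raw.hdr"))
    scene = phantom.make_scene((1012, 1012), seed=SEED)
    refs = phantom.make_reference_spectra(phantom.default_axis(), seed=SEED)

    pre, mask, report = preprocess.preprocess_pipeline(
        cube, constituents=refs.values
    )
    pd.DataFrame(report["stages"]).to_csv(
        os.path.join(RESULTS, "preprocess_stages.csv"), index=False
    )
    cubeio.write_cube(pre, os.path.join(SCRATCH, "cube_preprocessed.hdr"))
    np.save(os.path.join(SCRATCH, "mask.npy"), mask.mask)

    # majority class per FTIR pixel -> class-mean spectra
    f = round(cube.pixel_size / scene.pixel_size_hr)
    lab = scene.label_map
    lab_lr = np.array([
        [np.bincount(lab[i*f:(i+1)*f, j*f:(j+1)*f].ravel()).argmax()
         for j in range(pre.ncols)]
        for i in range(pre.nrows)
    ])
    np.save(os.path.join(SCRATCH, "labels_lowres.npy"), lab_lr)
    table = {"wavenumber": pre.axis}
    for cls in (1, 2, 3, 4):
        sel = (lab_lr == cls) & mask.mask
        if sel.any():
            table[phantom.CLASS_NAMES[cls]] = pre.data[sel].mean(axis=0)
    pd.DataFrame(table).to_csv(
        os.path.join(RESULTS, "class_mean_spectra.csv"), index=False
    )

    print(pd.DataFrame(report["stages"]).to_string(index=False))
    print(f"usable pixels: {mask.n_usable}/{mask.mask.size}")


if __name__ == "__main__":
    main()
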