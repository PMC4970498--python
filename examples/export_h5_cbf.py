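"""Export reduction results to multi-event HDF5 and byte-offset CBF.

HDF5 carries user-defined group layouts for indexing software that reads
multi-event files; CBF carries int32 images with the delta-based byte-offset
compression, plus a separate dark file holding the trained offset map.
"""

import tempfile
from pathlib import Path

import h5py
import numpy as np

from sfxprep import (
    OutputItem,
    batched_path,
    export_dark_cbf,
    read_cbf,
    train,
    write_cbf,
    write_multi_event_h5,
)

workdir = Path(tempfile.mkdtemp())
rng = np.random.default_rng(0)

# multi-event HDF5 with a user-defined group
events = [(i, {"frame": rng.poisson(10.0, size=(32, 32)).astype(np.int32),
               "n_peaks": int(rng.integers(0, 20))}) for i in range(5)]
h5path = write_multi_event_h5(
    events,
    [OutputItem("frame", group_path="entry/data"),
     OutputItem("n_peaks", dataset_name="peak_count", group_path="entry/result")],
    workdir / "run.h5", compress=True)
with h5py.File(h5path) as f:
    print(f"{h5path.name}: /entry/data/frame {f['/entry/data/frame'].shape}, "
          f"/entry/result/peak_count {f['/entry/result/peak_count'][()].tolist()}")

print("batched event files:",
      ", ".join(str(batched_path('out', i, files_per_dir=1000)) for i in (0, 999, 2500)))

# CBF round trip
img = rng.integers(-(10**6), 10**6, size=(64, 64)).astype(np.int32)
cbf = write_cbf(img, workdir / "image.cbf")
identical = np.array_equal(read_cbf(cbf), img)
ratio = cbf.stat().st_size / img.nbytes
print(f"{cbf.name}: byte-offset file is {ratio:.2f} x the raw int32 size; "
      f"read-back bit-identical: {identical}")

# dark CBF from a trained calibration
cal = train(rng.normal(100.0, 3.0, size=(50, 64, 64)))
dark = export_dark_cbf(cal, workdir / "dark.cbf")
print(f"{dark.name}: offset map rounded to int32, mean "
      f"{read_cbf(dark).mean():.1f} ADU (usable as a dark-current image downstream)")
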