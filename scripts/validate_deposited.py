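"""Optional validation against a directory of real back captures.

This script is for users who have downloaded the openly deposited back-scan
dataset (ETH Research Collection, DOI 10.3929/ethz-b-000615667) or who have
their own ground-truth captures in ASCII PLY/OBJ/XYZ (millimetres, y
vertical, z toward the sensor). It recomputes, on the real data, the
quantities the synthetic acceptance run can only emulate:

* the aggregate slice spectrum and its dominant frequency,
* shape MAE at cutoffs 0.1 / 0.05 / 0.02 mm^-1,
* symmetry-line MAE at 0.05 / 0.02 mm^-1 against the 0.1 mm^-1 reference.

Usage:
    python scripts/validate_deposited.py /path/to/clouds/ --out validation.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from backres import (
    aggregate_spectra,
    dominant_frequency,
    load_point_cloud,
    profile_spectrum,
    slice_stack,
    sweep_cutoffs,
)
from backres.symmetry import sweep_symmetry

SUFFIXES = {".ply", ".obj", ".xyz"}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("data_dir", type=Path)
    parser.add_argument("--out", type=Path, default=Path("validation.json"))
    parser.add_argument("--dx", type=float, default=0.5)
    parser.add_argument("--power-fraction", type=float, default=0.95)
    args = parser.parse_args()

    files = sorted(p for p in args.data_dir.iterdir()
                   if p.suffix.lower() in SUFFIXES)
    if not files:
        raise SystemExit(f"no point-cloud files found in {args.data_dir}")

    stacks = []
    for f in files:
        try:
            stacks.append(slice_stack(load_point_cloud(f), 5.0, 10.0, args.dx))
        except ValueError as exc:
            print(f"skipping {f.name}: {exc}")
    print(f"analyzing {len(stacks)} captures")

    spectra = [profile_spectrum(s) for st in stacks for s in st.slices]
    agg = aggregate_spectra(spectra)
    results = {
        "n_captures": len(stacks),
        "dominant_frequency_mm^-1": dominant_frequency(agg,
                                                       args.power_fraction),
        "max_contained_frequency_mm^-1": dominant_frequency(agg, 0.9999),
    }

    shape = sweep_cutoffs(stacks, [0.1, 0.05, 0.02], order=4)
    for fc, err in zip(shape.cutoffs, shape.errors):
        results[f"shape_mae_mm_at_fc_{fc:g}"] = float(err)

    sym = sweep_symmetry(stacks, [0.05, 0.02], reference_cutoff=0.1, order=4)
    for fc, err in zip(sym.cutoffs, sym.errors):
        results[f"symmetry_mae_mm_at_fc_{fc:g}"] = float(err)

    args.out.write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
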