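#!/usr/bin/env python
"""Generate the study's synthetic inputs.

Produces (a) three whole-neuron spindle morphologies spanning the
branching continuum (straight / sparse / profuse collaterals) at the
0.5 μm neuron-imaging z-step, and (b) the standard spine-segment phantom
(60 ground-truth spines at 0.8/μm, 0.1 μm isotropic voxels) in a
noiseless and an SNR-10 variant.

Tables and manifests go to results/; the bulky TIFF stacks go to
scratch/ (they are regenerated deterministically from the seeds).
"""

import argparse
import json
from pathlib import Path

import golgi3d as g
from golgi3d.pipeline import SimulateConfig, simulate, truth_table

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20220111)
    args = ap.parse_args()

    results = ROOT / "results"
    scratch = ROOT / "scratch" / "phantoms"
    results.mkdir(exist_ok=True)
    scratch.mkdir(parents=True, exist_ok=True)

    # whole-neuron morphologies
    for profile in ("straight", "sparse", "profuse"):
        cell = g.generate_spindle_swc(g.SpindleParams(
            branch_profile=profile, seed=args.seed))
        g.write_swc(cell, scratch / f"spindle_{profile}.swc")
    print(f"wrote 3 spindle morphologies (profiles) to {scratch}")

    # spine-segment phantoms
    summary = {}
    for noise in ("noiseless", "snr10"):
        out = scratch / f"fixture_{noise}"
        res = simulate(SimulateConfig(noise=noise), seed=args.seed, outdir=out)
        table = truth_table(res["truth"])
        table.to_csv(results / f"truth_spines_{noise}.csv", index=False)
        summary[noise] = {
            "n_spines": len(table),
            "dendrite_length_um": res["truth"].decorated_length,
            "density_per_um": res["truth"].density_per_um,
            "class_counts": table["class"].value_counts().to_dict(),
        }
        print(f"{noise}: {len(table)} spines on "
              f"{res['truth'].decorated_length:.1f} um of dendrite")
    (results / "phantom_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"ground-truth tables -> {results}")


if __name__ == "__main__":
    main()
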