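"""One-time seeded calibration of the default rater noise amplitudes.

Sweeps the per-mask global contouring-offset SD of the simulated rater panel
(with the local boundary-ripple amplitude fixed at its default) and measures
the inter-rater PE_%CV of mean cartilage thickness (Cg.Th) on the default
14-subject x 3-rater synthetic cohort.  The shipped default
(``earmorph.synthetic_data.DEFAULT_GLOBAL_AMPLITUDE``) is the amplitude whose
PE_%CV(Cg.Th) lands closest to the 9.5% target -- the upper part of the
single-digit-percent regime of manual ear-cartilage contouring at clinical
MRI resolution, where the contouring error is comparable to the
between-subject thickness spread.

Run (from the repository root):

    python scripts/calibrate_rater.py [--seed 20140821]
"""

import argparse
import time

from earmorph.reproducibility import precision_study
from earmorph.synthetic_data import PopulationSpec, default_raters, simulate_population

TARGET_PE_PCT_CV_TH = 9.5


def measure(bias_spread: float, global_amplitude: float, seed: int) -> dict:
    from earmorph.synthetic_data import RaterModel

    pop = PopulationSpec(seed=seed)
    raters = [
        RaterModel(bias=b * bias_spread, global_amplitude=global_amplitude, seed=i + 1)
        for i, b in enumerate((-1.0, 0.0, 1.0))
    ]
    study = simulate_population(pop, raters)
    result = precision_study(study.masks, compute_overlaps=False)
    return {m: (r.pe_pct_cv, r.icc) for m, r in result.reports.items()}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20140821)
    ap.add_argument(
        "--panels", type=str, nargs="*",
        help="bias_spread:global_amplitude pairs",
        default=["0.12:0.0", "0.10:0.06", "0.13:0.0"],
    )
    args = ap.parse_args()
    best = None
    for panel in args.panels:
        b, ga = (float(x) for x in panel.split(":"))
        t0 = time.time()
        out = measure(b, ga, args.seed)
        dist = abs(out["cg_th"][0] - TARGET_PE_PCT_CV_TH)
        if best is None or dist < best[1]:
            best = (panel, dist)
        msg = "  ".join(
            f"{m}: PE={pe:.2f}% ICC={icc:.3f}" for m, (pe, icc) in out.items()
        )
        print(f"bias_spread {b:.3f} ga {ga:.3f}: {msg}   ({time.time()-t0:.0f}s)",
              flush=True)
    print(f"closest to PE_th target {TARGET_PE_PCT_CV_TH}%: panel {best[0]}")


if __name__ == "__main__":
    main()
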