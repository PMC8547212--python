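"""Re-analysis of experimental DNA dilution-series measurements.

Optional companion script for users who have downloaded the deposited
measurement dataset (photon traces of RiboGreen-labelled dsDNA fragment
solutions; not shipped with this package).  For each fragment length it
expects a directory of trace files (format of ``msmr.io.read_trace``),
applies the full correction chain (dead time -> afterpulsing ->
background), fits the mSMR model with the isomerization term, averages
the per-trace fit parameters, and finally fits a power law
D = A * L^B to the diffusion coefficient vs fragment length.

Layout expected under --data-dir:

    <data-dir>/<length_bp>/<anything>.txt     one trace file per measurement

Usage:
    python scripts/reanalyze_dna.py --data-dir data/ --r 5 --r0-um 0.40 \
        --dead-time-ns 70 --afterpulse-prob 0.006 --background-cps 300 \
        --out report.json
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from msmr import DetectorParams, background_correct_curve, fit_msmr, msmr_curve
from msmr.fitting import aggregate_fits, diffusion_coefficient
from msmr.io import read_trace


def fit_power_law(x, y):
    """Fit y = A * x^B; returns (A, B, stderr_B).

    Linear least squares in log-log space would weight small values
    unevenly, so the fit is done directly on the power law with the
    log-log solution as starting point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive data")
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    popt, pcov = curve_fit(lambda x_, a, b: a * x_**b, x, y,
                           p0=[np.exp(intercept), slope], maxfev=10000)
    return float(popt[0]), float(popt[1]), float(np.sqrt(pcov[1, 1]))


def analyze_fragment_dir(frag_dir: Path, det: DetectorParams, r: float,
                         r0_um: float) -> dict:
    results = []
    for trace_path in sorted(frag_dir.glob("*.txt")):
        trace = read_trace(trace_path)
        curve = msmr_curve(trace, corrections=det)
        if det.background_rate > 0:
            curve = background_correct_curve(curve, det.background_rate)
        results.append(fit_msmr(curve, include_iso=True, r=r))
    if len(results) < 2:
        raise SystemExit(f"{frag_dir}: need at least 2 traces, found {len(results)}")
    agg = aggregate_fits(results)
    agg["D_um2_s"] = diffusion_coefficient(agg["mean"]["tau_d"], r0_um)
    return agg


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--r", type=float, required=True,
                        help="PSF aspect ratio from calibration")
    parser.add_argument("--r0-um", type=float, required=True)
    parser.add_argument("--dead-time-ns", type=float, default=70.0)
    parser.add_argument("--afterpulse-prob", type=float, default=0.006)
    parser.add_argument("--background-cps", type=float, default=0.0)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args(argv)

    det = DetectorParams(t_dead=args.dead_time_ns * 1e-9,
                         p_afterpulse=args.afterpulse_prob,
                         background_rate=args.background_cps)
    lengths, coefficients, per_fragment = [], [], {}
    for frag_dir in sorted(args.data_dir.iterdir()):
        if not frag_dir.is_dir() or not frag_dir.name.isdigit():
            continue
        agg = analyze_fragment_dir(frag_dir, det, args.r, args.r0_um)
        per_fragment[frag_dir.name] = agg
        lengths.append(int(frag_dir.name))
        coefficients.append(agg["D_um2_s"])
    if len(lengths) < 3:
        raise SystemExit("need at least 3 fragment lengths for the power-law fit")

    amp, exponent, stderr = fit_power_law(lengths, coefficients)
    report = {"per_fragment_bp": per_fragment,
              "power_law": {"A": amp, "B": exponent, "B_stderr": stderr}}
    text = json.dumps(report, indent=2, sort_keys=True)
    if args.out:
        args.out.write_text(text + "\n")
        print(f"wrote {args.out}")
    else:
        print(text)
    return 0


if __name__ == "__main__":
    sys.exit(main())
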