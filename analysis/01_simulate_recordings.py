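"""Simulate all study recordings (traces + ground truth) into scratch/.

Each recording is a seeded ionic-current trace with known event populations:
single-peptide calibration measurements, mixtures for resolution and
classification, and the modified-sample / equimolar-mixture pair used for
cyclization quantification.
"""

import argparse

from nanopept import simulate
from nanopept.io import write_trace, write_truth

import studyconfig as sc


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    for name, cfg in sc.recordings(args.seed).items():
        trace, truth = simulate(cfg)
        write_trace(trace, sc.trace_prefix(name))
        write_truth(truth, sc.truth_path(name))
        occupancy = sum(ev.end - ev.start for ev in truth) / trace.samples.size
        print(
            f"{name:14s} {cfg.duration:5.0f} s  {len(truth):5d} events  "
            f"occupancy {100 * occupancy:4.1f}%"
        )
    print(f"\nrecordings written under {sc.trace_prefix('')}")


if __name__ == "__main__":
    main()
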