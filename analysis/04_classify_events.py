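"""Classify SyncA2-like events by logistic regression on three features.

The cyclized form (SyncA2) fluctuates between two current sub-levels during
an event, so its sigma_b is systematically higher than the linear form's
(SyncA2-L) even where the I_ex% clusters overlap.  Events with
50% < I_ex% < 90% from the two single-peptide measurements train the model;
it is then applied to the mixture measurement and scored against the
simulation's ground truth as per-class true-positive rates.
"""

import argparse
import json
import warnings

from nanopept import evaluate, filter_events, predict, train_classifier
from nanopept.io import read_events, read_truth, write_model
from nanopept.simulate import label_events_by_truth

import studyconfig as sc


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1, help="selects the recording set")
    args = ap.parse_args()
    del args

    labeled = []
    for rec, label in (("synca2", "SyncA2"), ("synca2_l", "SyncA2-L")):
        events = filter_events(read_events(sc.events_path(rec)))
        labeled += [(e, label) for e in events]
        print(f"{rec:12s} {len(events):4d} training events ({label})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = train_classifier(labeled)
    write_model(model, sc.SCRATCH / "clusters" / "synca2_model.json")

    mix_events = filter_events(read_events(sc.events_path("synca2_mix")))
    truth = read_truth(sc.truth_path("synca2_mix"))
    truth_labels = label_events_by_truth(truth, [(e.start, e.end) for e in mix_events])
    keep = [i for i, lab in enumerate(truth_labels) if lab is not None]
    mix_events = [mix_events[i] for i in keep]
    truth_labels = [truth_labels[i] for i in keep]

    pred, _ = predict(model, mix_events)
    summary = evaluate(pred, truth_labels)
    print(f"\nmixture events scored: {summary.n}")
    for cls in summary.classes:
        print(f"  TPR {cls:10s} {summary.tpr_pct[cls]:5.1f}%")

    sc.RESULTS.mkdir(parents=True, exist_ok=True)
    out = sc.RESULTS / "classification.json"
    out.write_text(
        json.dumps(
            {
                "classes": list(summary.classes),
                "tpr_pct": {c: round(summary.tpr_pct[c], 1) for c in summary.classes},
                "confusion": summary.counts.tolist(),
                "n_mixture_events": summary.n,
                "weights": model.weights.tolist(),
                "feature_names": list(model.feature_names),
            },
            indent=1,
        )
        + "\n"
    )
    print(f"\nclassification report -> {out}")


if __name__ == "__main__":
    main()
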