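"""Train the two models once, run them over the rendered cohort, aggregate.

Mirrors the deployment path: models are trained on the independent annotated
corpus (never on cohort data, and blind to group membership), then applied
to every rendered minute of every participant-day.  Frame probabilities
become minute calls (mean probability > 0.5), daily and time-of-day
percentages, and the wearer share of speech frames.  The estimated profile
table and its agreement with ground truth go to results/.
"""

import dataclasses
import importlib.util
import sys
import time
from pathlib import Path

import pandas as pd

from wristmic.classify import train_speech_detector, train_wearer_classifier
from wristmic.corpus import build_training_corpus, prepare_annotated
from wristmic.pipeline import run_study

RESULTS = Path(__file__).resolve().parents[1] / "results"
CORPUS_SEED = 0
TRAIN_SEED = 0


def cohort_config():
    """Same cohort parameters as 03_simulate_cohort, audio rendered this time."""
    spec = importlib.util.spec_from_file_location("sim03", Path(__file__).with_name("03_simulate_cohort.py"))
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return dataclasses.replace(mod.COHORT, render_audio=True)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    t0 = time.time()
    ann = prepare_annotated(build_training_corpus(seed=CORPUS_SEED))
    speech_model = train_speech_detector(ann, seed=TRAIN_SEED)
    wearer_model = train_wearer_classifier(ann, seed=TRAIN_SEED)
    print(f"models trained on the annotated corpus in {time.time()-t0:.0f}s")

    t0 = time.time()
    est, truth = run_study(cohort_config(), speech_model=speech_model, wearer_model=wearer_model)
    est.to_csv(RESULTS / "profiles.csv", index=False, float_format="%.6f")
    print(f"cohort rendered and analyzed in {time.time()-t0:.0f}s -> {RESULTS / 'profiles.csv'}")

    merged = est.merge(truth, on=["participant_id", "group"], suffixes=("_est", "_true"))
    report = []
    for col in ("speech_pct", "wearer_pct"):
        err = (merged[f"{col}_est"] - merged[f"{col}_true"]).abs()
        report.append({"measure": col, "mean_abs_err": err.mean(), "max_abs_err": err.max()})
    errors = pd.DataFrame(report)
    errors.to_csv(RESULTS / "recovery_errors.csv", index=False, float_format="%.4f")
    print(errors.to_string(index=False))
    for g in ("case", "control"):
        sub = est[est["group"] == g]
        print(f"  {g:8s} estimated speech {sub['speech_pct'].mean():5.2f}% "
              f"wearer {sub['wearer_pct'].mean():5.2f}%")


if __name__ == "__main__":
    sys.exit(main())
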