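"""Generate the synthetic sentence-production cohort and record its design.

The cohort mirrors the study layout: 18 speakers x 4 sentence types x 2
repetitions = 144 trigger-plus-target recordings, with two speakers who
never inhale before the target and 14 further un-breathed utterances baked
into the *design* (the analysis must rediscover them from the signals).

Writes results/cohort_design.csv (one row per utterance) and prints the
design counts.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), os.pardir, "src"))

from breathkin.study import generate_cohort

OUT = os.path.join(os.path.dirname(__file__), os.pardir, "results")
SEED = 0


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    cohort = generate_cohort(seed=SEED)
    rows = [{
        "utterance_id": u.utterance_id,
        "speaker": u.speaker,
        "sentence_type": u.sentence_type,
        "repetition": u.repetition,
        "has_inhalation": u.has_inhalation,
        "rip_samples": len(u.session.rip),
        "duration_s": round(u.session.rip.duration_s, 3),
    } for u in cohort]
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "cohort_design.csv"), index=False)
    print(f"generated {len(df)} utterances "
          f"({df['speaker'].nunique()} speakers, seed {SEED})")
    print("un-breathed by design:", int((~df["has_inhalation"]).sum()))
    print(df.groupby("sentence_type")["has_inhalation"].agg(["count", "sum"]))


if __name__ == "__main__":
    main()
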