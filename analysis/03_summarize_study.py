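#!/usr/bin/env python
"""Treatment x period summaries, RCBD ANOVA, and derived statistics.

Aggregates results/metrics/ to paddock x period cells, fits the
fixed-effects RCBD model per metric, and writes the treatment tables,
the ANOVA table, and derived statistics to results/summaries/.
"""

import json
import pathlib

from grazetrack.pipeline import summarize

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    res = summarize(str(ROOT / "metrics"), str(ROOT / "study" / "design.csv"), str(ROOT / "summaries"))
    for col in ("distance_m_per_day", "resting_pct", "grazing_pct", "traveling_pct"):
        a = res["anova"][col]
        means = ", ".join(
            f"{t}={m:.1f}{a.letters[t]}" for t, m in a.treatment_means.items()
        )
        print(f"{col}: {means}  (treatment p={a.p_treatment:.2g}, SEM={a.sem:.2f})")
    print(json.dumps(res["derived"], indent=2))
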