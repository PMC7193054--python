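#!/usr/bin/env python
"""Dose-response re-test and electrophysiological confirmation.

Re-tests the intersection candidates at 1/10/100 uM for a concentration-
dependent response, then records LFP epochs for the confirmed candidates
and the vehicle group, detects epileptiform events, and compares total
event frequencies by one-way ANOVA with Dunnett tests against vehicle.
"""

from pathlib import Path

import pandas as pd

from zfscreen import ScreenConfig
from zfscreen import io as zio
from zfscreen.pipeline import (
    confirmation_concentration,
    run_dose_response,
    run_ep_confirmation,
)

SEED = 20
RESULTS = Path(__file__).parents[1] / "results"


def main() -> None:
    ds = zio.load_dataset(RESULTS / "dataset")
    cfg = ScreenConfig(sim=ds.cfg)
    candidates = (RESULTS / "intersection.txt").read_text().split()

    panels = run_dose_response(ds, candidates, cfg)
    dependent = {
        cid: confirmation_concentration(p)
        for cid, p in panels.items()
        if p.concentration_dependent and confirmation_concentration(p) is not None
    }
    print(f"dose-response: {len(dependent)}/{len(candidates)} candidates "
          f"concentration dependent")

    final, stat, table = run_ep_confirmation(ds, dependent, cfg, seed=SEED)
    table.to_csv(RESULTS / "ep_event_rates.csv", index=False)
    if stat is not None:
        rows = [
            {"group": g.group_id, "mean": g.mean, "sem": g.sem, "n": g.n,
             "dunnett_p": g.p_adjusted, "significant": g.significant}
            for g in stat.per_group
        ]
        pd.DataFrame(rows).to_csv(RESULTS / "ep_dunnett.csv", index=False)
        print(f"ANOVA: F({stat.df_between},{stat.df_within}) = {stat.F:.2f}, "
              f"p = {stat.p_value:.2g}")
    print(f"confirmed final hits: {final} -> results/ep_dunnett.csv")
    (RESULTS / "final_hits.txt").write_text("\n".join(final) + "\n")


if __name__ == "__main__":
    main()
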