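#!/usr/bin/env python
"""Primary dual-concentration behavioral screen and intersection.

Runs the 250 uM and 10 uM locomotion screens over the simulated library,
applies the hit rule (>=40% mean-velocity reduction, >=50% of fish at
stage 0/I, no acute toxicity), and intersects the positive sets.  Writes
the per-compound stage tables under results/.
"""

from pathlib import Path

from zfscreen import ScreenConfig
from zfscreen import io as zio
from zfscreen.pipeline import intersect_primary, run_primary_stage

RESULTS = Path(__file__).parents[1] / "results"


def main() -> None:
    ds = zio.load_dataset(RESULTS / "dataset")
    cfg = ScreenConfig(sim=ds.cfg)
    hi, lo = cfg.primary_concentrations

    t_hi = run_primary_stage(ds, hi, cfg)
    t_lo = run_primary_stage(ds, lo, cfg)
    n = len(ds.compound_ids)
    for table in (t_hi, t_lo):
        pos, tox = table.positives, table.toxic
        print(f"{table.concentration:g} uM: {len(pos)} positive "
              f"({100*len(pos)/n:.0f}%), {len(tox)} toxic ({100*len(tox)/n:.0f}%)")
        table.calls.to_csv(RESULTS / f"primary_{table.concentration:g}uM.csv",
                           index=False)
        table.vehicle.to_csv(RESULTS / f"vehicle_{table.concentration:g}uM.csv",
                             index=False)

    candidates = intersect_primary(t_hi, t_lo)
    (RESULTS / "intersection.txt").write_text("\n".join(candidates) + "\n")
    print(f"intersection (positive at both concentrations): "
          f"{len(candidates)} compounds -> results/intersection.txt")


if __name__ == "__main__":
    main()
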