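"""Estimate the full battery of care-choice models.

Runs, on ``results/indices.csv``:

* the baseline logits (each tie index bare, then with the ten controls),
* the robustness refits (clan / friend replacements; probit re-estimation),
* the east/mid-west and urban/rural heterogeneity splits,
* the mechanism triple (index -> medical insurance -> care choice,
  then restricted to healthy respondents),

writes one CSV and one aligned text table per battery under ``results/``,
and prints the baseline and mechanism tables.
"""

from pathlib import Path

from strongties import read_table, write_table
from strongties.glm import (
    baseline_battery,
    battery_frame,
    heterogeneity_battery,
    mechanism_battery,
    render_battery,
    robustness_battery,
)


def main() -> None:
    root = Path(__file__).resolve().parents[1] / "results"
    table = read_table(root / "indices.csv")

    batteries = {
        "baseline": baseline_battery(table),
        "robustness": robustness_battery(table),
        "heterogeneity": heterogeneity_battery(table),
    }
    mech = mechanism_battery(table)
    batteries["mechanism"] = [f for fits in mech.values() for f in fits]

    for name, fits in batteries.items():
        write_table(battery_frame(fits), root / f"table_{name}.csv")
        (root / f"table_{name}.txt").write_text(render_battery(fits, title=name) + "\n")

    print(render_battery(batteries["baseline"], title="baseline care-choice logits"))
    print()
    print(render_battery(batteries["mechanism"],
                         title="mechanism: tie index -> medical insurance -> care choice"))


if __name__ == "__main__":
    main()
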