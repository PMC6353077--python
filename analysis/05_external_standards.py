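#!/usr/bin/env python
"""Cross-application of modern cremated reference standards.

Recomputes the non-overlap index D for the two bundled contemporary
cremated series from their printed summaries, then applies their
density-intersection cut-offs to the (ancient-like) synthetic study series.
Because the modern series run several millimetres larger, their cut-offs
sit high in the ancient distributions: female classifications stay almost
perfect while a large share of males is misclassified — the signature of
applying a population-foreign standard.

Writes results/external_D.csv and results/external_application.csv.
"""

from pathlib import Path

import pandas as pd

import cremsex as cs

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = cs.read_measurement_table(OUT / "synthetic_measurements.csv")

    d_rows, app_rows = [], []
    for name in ("external-modern-1", "external-modern-2"):
        std = cs.load_reference_registry(name)
        for code in std.codes:
            ts = std[code]
            d_rows.append({
                "standard": name, "trait": code,
                "D": cs.cm_D(ts.male.mean, ts.male.sd, ts.female.mean, ts.female.sd),
                "published_D": ts.published["D"],
            })
            res = cs.apply_external_standard(table, code, std)
            app_rows.append({
                "standard": name, "trait": code,
                "cutoff_mm": res["cutoff"], **res["metrics"],
            })

    pd.DataFrame(d_rows).to_csv(OUT / "external_D.csv", index=False)
    app = pd.DataFrame(app_rows)
    app.to_csv(OUT / "external_application.csv", index=False)

    print("external standards applied to the synthetic ancient-like series:")
    for _, row in app.iterrows():
        print(f"  {row['standard']} {row.trait}: cut-off {row.cutoff_mm:.2f} mm -> "
              f"accuracy {row.accuracy:.1f}%, precision M {row.precision_male:.1f}%, "
              f"precision F {row.precision_female:.1f}%")
    print("male precision collapses while female precision stays high: "
          "modern cut-offs overshoot the smaller ancient male distributions")


if __name__ == "__main__":
    main()
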