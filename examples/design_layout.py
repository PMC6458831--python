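"""Generate one year's split-plot Smarthouse layouts.

447 unreplicated test lines split over the NE/NW houses; each house is a
6-zone x 4-lane x 22-position grid whose consecutive cart pairs form main
plots carrying the two water treatments. Check main plots follow the
6-per-zone / 3-or-4-per-column quotas.
"""

import pandas as pd

from namgwas import generate_year, validate_layout

lines = [f"HEB_{i:04d}" for i in range(447)]
layouts = generate_year(lines, seed=7)

for house, layout in layouts.items():
    checks = layout[layout["is_check"]]
    print(f"{house}: {layout['main_plot_id'].nunique()} main plots, "
          f"{len(layout)} carts, "
          f"{checks['main_plot_id'].nunique()} check main plots, "
          f"{layout.loc[~(layout['is_check'] | layout['is_recurrent']), 'genotype'].nunique()} test lines")
    print(f"  checks per column: "
          f"{sorted(checks.groupby('column')['main_plot_id'].nunique())}")
    print(f"  violations: {validate_layout(layout) or 'none'}")

both = pd.concat(layouts.values())
per_trt = both[both["is_check"]].groupby("treatment").size()
print(f"check carts per treatment across both houses: {per_trt.to_dict()}")
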