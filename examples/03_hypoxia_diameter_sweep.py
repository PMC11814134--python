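"""How large may a spheroid grow before hypoxia? A diameter sweep.

Steady minimum oxygen pressure falls as the spheroid diameter grows; the
diameters at which the decreasing isotonic fit crosses 100 mmHg (end of the
safe range) and 50 mmHg (onset of necrosis) bound the hypoxia-forming
range.  The closed form predicts crossings at 309.8 μm and 464.8 μm.
"""

import numpy as np

from oxispheroid import SimulationConfig
from oxispheroid.analysis import classify_thresholds, diameter_sweep

config = SimulationConfig()
diameters = np.arange(200.0, 481.0, 40.0)

sweep = diameter_sweep("single", diameters, cells_per_radius=12, config=config)
print(sweep.table.to_string(index=False,
                            formatters={"min_pressure_mmHg": "{:.2f}".format}))

report = classify_thresholds(sweep, thresholds=(50.0, 100.0))
print(f"\nsafe range:            d <= {report.safe_max_um:.1f} um (min pO2 > 100 mmHg)")
print(f"hypoxia forming:       {report.forming_range_um[0]:.1f} - "
      f"{report.forming_range_um[1]:.1f} um")
print(f"necrosis expected:     d >= {report.necrotic_min_um:.1f} um (min pO2 < 50 mmHg)")
# A bioprinting practitioner would pick spheroids below the safe boundary,
# e.g. 250-300 um, leaving margin before hypoxic cores form.
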