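"""Generate a synthetic stream site bundle with known ground truth.

Shows the generator's analytic expectations (sinuosity by quadrature,
pool reaches, per-metric categories) and writes the GeoJSON/CSV bundle
a downstream assessment would consume.
"""

import json
import tempfile
from pathlib import Path

from streamhab import io as shio
from streamhab.synthetic import MeanderSpec, PiecewiseProfile, generate_site

spec = MeanderSpec(
    axis_length=200.0, amplitude=10.0, wavelength=100.0,
    erosion_left=PiecewiseProfile(0.0, ((90.0, 110.0, 1.2),)),
    pool_reaches=((30.0, 55.0),),
)
site, banks, layers, truth = generate_site(spec)

print(f"meandered length {truth.length:.2f} m over {truth.straight_dist:.2f} m "
      f"-> sinuosity {truth.sinuosity:.4f} (arc-length quadrature)")
print(f"pool reaches: {[(p.s_start, p.s_end) for p in truth.pool_intervals]}")
print("expected site categories:",
      json.dumps(truth.expected_categories["categories"], indent=2))

out = Path(tempfile.mkdtemp())
shio.write_site_plan(site, out / "site.geojson")
shio.write_banks(banks, out / "banks.geojson")
print(f"wrote {sorted(p.name for p in out.iterdir())} to {out}")
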