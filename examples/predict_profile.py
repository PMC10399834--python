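"""Evaluate the landing-height regressions at the analysis heights.

20/40/60 cm are inside the measured range; 126 cm is the supra-
physiological extrapolation at which the damage search operates.
"""

import warnings

from kneeland import regression as rg

print(rg.models_to_frame().to_string(index=False))
print()
for h in (20, 40, 60, 126):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        prof = rg.predict_profile(h)
    s = prof.sagittal
    print(f"h={h:4d} cm: knee flexion {s['knee_flex_angle']:6.2f} deg, "
          f"knee moment {s['knee_flex_moment']:5.3f} N*m/kg, "
          f"vGRF {s['vgrf']:5.2f} BW")
print("vGRF is the peak vertical ground reaction force in body weights; "
      "moments are body-mass normalized. Values above 60 cm are "
      "extrapolations of the fitted power/log/exponential models.")
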