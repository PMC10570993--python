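# Eight named variability classes over the default two-ring reference unit
# (radius 53.7 nm, ring separation 50 nm).  The 14-degree twist and 9-fold
# symmetry values come from reported NPC observations; the remaining
# magnitudes (smaller radius, smaller ring distance, shift SD, tilt
# concentration, elongation ratio) are editable defaults chosen to produce
# clearly visible but non-overlapping deformations - adjust them to your
# hypothesis.
reference: {}
smaller_radius:
  mean_radius: 48.7      # nm, 5 nm below the reference mean radius
smaller_height:
  height: 40.0           # nm CR-NR distance, 10 nm below the reference 50
elongated:
  elongation_q: 0.8      # short/long axis ratio of the target ellipse
twist_14deg:
  twist_deg: 14.0        # azimuthal CS-NS twist
ninefold:
  s: 9                   # 9-fold rotational symmetry (greater diameter)
shifted:
  shift_sd: 3.0          # nm lateral SD per side
tilted:
  tilt_kappa: 50.0       # von Mises-Fisher concentration; smaller = more tilt
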