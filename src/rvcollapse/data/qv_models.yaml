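# Qualifying-variant (QV) model registry: ten dominant models and one
# recessive model.  Every field is overridable; point the engine at a copy
# of this file to change thresholds.
#
# Fields per model:
#   mode:                        dominant | recessive
#   consequences:                ptv | missense | synonymous groups (expanded
#                                to term sets by the engine)
#   max_gnomad_maf:              gnomAD MAF ceiling (popmax when available if
#                                use_popmax, else global)
#   max_internal_maf:            within-stratum MAF ceiling on QC-passed calls
#   require_damaging_prediction: missense variants must carry the damaging
#                                predictor flag
#   use_popmax:                  prefer the gnomAD popmax MAF when present
ptv:
  mode: dominant
  consequences: [ptv]
  max_gnomad_maf: 0.001
  max_internal_maf: 0.001
  require_damaging_prediction: false
  use_popmax: true
ptv5pcnt:
  mode: dominant
  consequences: [ptv]
  max_gnomad_maf: 0.05
  max_internal_maf: 0.05
  require_damaging_prediction: false
  use_popmax: true
UR:
  mode: dominant
  consequences: [ptv, missense]
  max_gnomad_maf: 0.0
  max_internal_maf: 0.0005
  require_damaging_prediction: false
  use_popmax: true
URdmg:
  mode: dominant
  consequences: [ptv, missense]
  max_gnomad_maf: 0.0
  max_internal_maf: 0.0005
  require_damaging_prediction: true
  use_popmax: true
raredmg:
  mode: dominant
  consequences: [missense]
  max_gnomad_maf: 0.0005
  max_internal_maf: 0.0005
  require_damaging_prediction: true
  use_popmax: true
flexdmg:
  mode: dominant
  consequences: [ptv, missense]
  max_gnomad_maf: 0.001
  max_internal_maf: 0.001
  require_damaging_prediction: true
  use_popmax: true
flexnonsyn:
  mode: dominant
  consequences: [ptv, missense]
  max_gnomad_maf: 0.001
  max_internal_maf: 0.001
  require_damaging_prediction: false
  use_popmax: true
dmg5pcnt:
  mode: dominant
  consequences: [ptv, missense]
  max_gnomad_maf: 0.05
  max_internal_maf: 0.05
  require_damaging_prediction: true
  use_popmax: true
rarenonsyn:
  mode: dominant
  consequences: [ptv, missense]
  max_gnomad_maf: 0.005
  max_internal_maf: 0.005
  require_damaging_prediction: false
  use_popmax: true
syn:
  mode: dominant
  consequences: [synonymous]
  max_gnomad_maf: 0.0005
  max_internal_maf: 0.0005
  require_damaging_prediction: false
  use_popmax: true
rec:
  mode: recessive
  consequences: [ptv, missense]
  max_gnomad_maf: 0.01
  max_internal_maf: 0.01
  require_damaging_prediction: true
  use_popmax: true
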