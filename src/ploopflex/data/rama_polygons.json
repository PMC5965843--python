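{
  "version": "1.0",
  "comment": "Coarse Ramachandran region polygons (vertex lists in degrees, phi/psi in (-180,180]). The classification contract is polygon membership with closed boundaries, not probability density. 'glycine' polygons are the phi>0 mirror regions accessible only to glycine; non-glycine residues falling there classify as outliers.",
  "general_favored": [
    {"id": "alpha", "vertices": [[-160, -80], [-160, 10], [-45, 10], [-45, -80]]},
    {"id": "beta", "vertices": [[-180, 90], [-180, 180], [-45, 180], [-45, 90]]},
    {"id": "beta-wrap", "vertices": [[-180, -180], [-180, -150], [-45, -150], [-45, -180]]}
  ],
  "general_allowed": [
    {"id": "alpha-allowed", "vertices": [[-180, -120], [-180, 30], [-20, 30], [-20, -120]]},
    {"id": "beta-allowed", "vertices": [[-180, 60], [-180, 180], [-20, 180], [-20, 60]]},
    {"id": "beta-wrap-allowed", "vertices": [[-180, -180], [-180, -140], [-20, -140], [-20, -180]]},
    {"id": "left-alpha", "vertices": [[20, -20], [20, 90], [100, 90], [100, -20]]}
  ],
  "glycine": [
    {"id": "gly-mirror-beta", "vertices": [[45, 120], [45, 180], [180, 180], [180, 120]]},
    {"id": "gly-mirror-beta-wrap", "vertices": [[45, -180], [45, -120], [180, -120], [180, -180]]},
    {"id": "gly-mirror-alpha", "vertices": [[45, -100], [45, 60], [180, 60], [180, -100]]}
  ]
}
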