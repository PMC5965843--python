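"""Classify a phosphate-binding loop as catalytically active or inactive.

In an active P-loop the backbone amide N-H groups of the central motif
residues point into the active-site pocket, creating the positive
electrostatic cradle that binds the substrate phosphate; in the inactive
conformation they point away. The classifier scores the cosine between each
pseudo-hydrogen N-H direction and the direction to the pocket center.
"""

import ploopflex as pf

for truth in ("active", "inactive"):
    fixture = pf.make_ploop_fixture(truth)  # ligand placed on the known side
    state = pf.ploop_state(fixture, motif_start=1)
    cos = ", ".join(f"{o.residue[1]}:{o.cosine:+.2f}" for o in state.orientations)
    print(f"built as {truth:8s} -> classified {state.state:8s} "
          f"(mean cosine {state.mean_cosine:+.3f}; per-residue {cos}; "
          f"pocket: {state.pocket_tag})")
# Positive cosines mean amides facing the pocket (active); negative mean
# facing away (inactive). The call requires 3 of the 4 central residues to
# agree with the mean beyond a +/-0.2 margin, otherwise it is indeterminate.
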