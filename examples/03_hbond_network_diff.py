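"""Difference the hydrogen-bond networks of two conformers.

A conformational switch typically re-wires hydrogen bonds: a bond present
in one form is absent from the other. Here the second structure is the
first with one peptide bond flipped, which breaks/retargets the local
amide-carbonyl contacts.
"""

import ploopflex as pf

spec = pf.PeptideSpec.uniform("HCMGGLGR", phi=-70.0, psi=-30.0)
form_a, form_b = pf.make_flip_pair(spec, flip_at=4)

diff = pf.compare_hbond_networks(form_a, form_b)


def show(tag, bonds):
    for h in bonds:
        print(f"  {tag}  {h.donor[2]}{h.donor[1]}.{h.donor[3]} -> "
              f"{h.acceptor[2]}{h.acceptor[1]}.{h.acceptor[3]} "
              f"({h.distance:.2f} A, donor angle {h.donor_angle:.0f} deg)")


print(f"{len(diff.shared)} bonds shared, {len(diff.only_in_a)} only in A, "
      f"{len(diff.only_in_b)} only in B")
show("A only:", diff.only_in_a)
show("B only:", diff.only_in_b)
# Bonds are matched by donor/acceptor residue number + atom name, so a bond
# that migrates to a new partner appears as one loss plus one gain.
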