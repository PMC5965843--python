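"""Count side-chain carbon-carbon packing contacts.

Tight hydrophobic packing is a standard correlate of thermostability: a
buried side chain making many carbon-carbon contacts within 4.5 A is hard
to melt out. The count is over unordered atom pairs (side-chain carbon of
the residue x any carbon of any other residue); alternate conventions are
reported alongside.
"""

import ploopflex as pf

# toy peptides carry backbone + CB only, so counts here are CB-CB/CB-backbone
# pairs; on a full crystal structure every side-chain carbon contributes
helix = pf.build_peptide(pf.PeptideSpec.uniform("LLLLLLLLLLLL", -57.0, -47.0))

profile = pf.contact_profile(helix, cutoff=4.5)
print(profile.to_string(index=False))

cc = pf.count_cc_contacts(helix, residue=6, cutoff=4.5)
print(f"\nresidue 6 ({cc.res_name}): {cc.count} C-C pairs at {cc.cutoff} A")
print(f"alternate conventions: {cc.alternates}")
# 'no_neighbors' excludes sequence-adjacent residues, 'partner_atoms' counts
# distinct partner carbons, 'partner_residues' distinct partner residues --
# published contact numbers can follow any of these conventions.
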