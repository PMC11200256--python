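"""Locate the 24 pocket residues of a query rhodopsin by alignment.

Uses the packaged bacteriorhodopsin reference (24 annotated positions
including the Schiff-base lysine K216) and transfers the positions onto
a query that carries an N-terminal extension and a point mutation —
the usual situation for homologues and engineered variants.
"""

import rhopocket as rp

spec = rp.load_default_pocket_spec()
print(f"reference: {spec.ref_id}, {len(spec.ref_sequence)} residues")
print(f"annotated pocket positions: {spec.pocket_positions}")

# query = reference with a 5-residue tag and one substitution near the pocket
query = "GSGSG" + spec.ref_sequence[:88] + "A" + spec.ref_sequence[89:]
aln = rp.global_align(query, spec.ref_sequence)
print(f"alignment score: {aln.score:.1f}")

indices = rp.map_pocket_positions(aln, spec)
print(f"mapped query positions: {indices}")
# the tag shifts every pocket position by exactly 5
assert indices == [p + 5 for p in spec.pocket_positions]
print("all 24 positions recovered, shifted by the 5-residue tag")
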