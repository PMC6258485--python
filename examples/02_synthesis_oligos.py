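"""From a spacer to synthesis-ready DNA and back through BbsI digestion.

Shows the 77-mer pool oligo (39-nt flank + N19 + 19-nt flank), the 24-bp
Golden-Gate insert it releases on BbsI digestion, and the equivalent
annealed 24-mer pair used for individual cloning.
"""

from crispra_screen import oligo_tools as ot

spacer = "ACGTTAGCATCGGATCATA"

oligo = ot.format_synthesis_oligo(spacer, guide_id="demo")
print(f"77-mer pool oligo ({len(oligo.sequence)} nt):")
print(" ", oligo.sequence)

insert = ot.bbsi_digest(oligo)
print(f"\nBbsI insert top strand ({len(insert.top_strand)} nt):", insert.top_strand)
print("5' overhangs:", insert.left_overhang, "/", insert.right_overhang)
# CACC / AAAC are complementary to the BbsI-cut expression vector, so the
# insert ligates directionally; top_strand[4:] is the cloned G + spacer.

top, bottom = ot.format_annealed_pair(spacer)
print("\nAnnealed pair for individual cloning:")
print("  top:   ", top)
print("  bottom:", bottom)
print("duplex identical to digested insert:",
      ot.annealed_duplex(top, bottom) == insert)
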