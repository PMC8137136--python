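"""Turn a chosen targeting sequence into the two cloning oligos.

Prints the top/bottom oligos with their CACC/AAAC Golden-Gate overhangs
(complementary to the BbsI-cut sgRNA vector), the spacer Tm, and the
thermal-cycler annealing program.
"""

from pombe_crispri import make_oligo_pair
from pombe_crispri.oligos import PROTOCOL_NOTES, schedule_text

spacer = "ATGTTGGATTACTTCGTTAA"  # example 20-nt targeting sequence
pair = make_oligo_pair(spacer)

print(f"spacer : 5'-{spacer}-3'")
print(f"top    : 5'-{pair.top}-3'")
print(f"bottom : 5'-{pair.bottom}-3'")
print(f"Tm     : {pair.tm_c:g} degC (Wallace rule)")
print()
print(schedule_text(pair.schedule))
print()
print(PROTOCOL_NOTES)
print()
print("# The annealed duplex carries 4-nt 5' overhangs (CACC top, AAAC")
print("# bottom) that ligate directionally into the BbsI-cut vector.")
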