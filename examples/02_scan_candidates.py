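"""Scan a small sequence for NGG-adjacent candidate guides on both strands.

Every 20-nt window (here 6-nt, to keep the toy readable) followed by an NGG
motif is a candidate sgRNA target; minus-strand candidates are reported
guide-oriented with forward-reference coordinates.
"""

from offscan import GenomeSequence, parse_pam, scan_candidates

seq = "TTACGTACGTAGGCCTTAGGAACCTTGCCA"
genome = [GenomeSequence("toy", seq)]
sites = scan_candidates(genome, parse_pam("NGG"), spacer_len=6)

print(f"{len(sites)} candidate sites in {len(seq)} bp (both strands):")
print("site_id  start  strand  spacer   pam")
for s in sites:
    print(f"{s.site_id:>7}  {s.start:>5}  {s.strand:>6}  {s.spacer}  {s.pam_seq}")

# Each row is one PAM-adjacent spacer: 'start' is the 0-based forward
# coordinate of the spacer; on the '-' strand the spacer shown is the
# reverse complement of the reference, i.e. the sequence the guide RNA
# would actually match.
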