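"""Build an FM-index on a toy string and run a backward search.

The classic banana example: suffix array, BWT, C array, and locating all
occurrences of 'ana' in O(|query|) interval updates.
"""

from offscan import build_fm_index

fm = build_fm_index("banana$", alphabet=("a", "b", "n"))

print("text          :", fm.text.symbols)
print("suffix array  :", [int(i) for i in fm.sa])
print("BWT           :", fm.bwt)
print("C array       :", fm.c_array())

iv = fm.exact_search("ana")
print(f"interval of 'ana' : [{iv.sp}, {iv.ep}]  ({len(iv)} occurrences)")
print("text positions    :", fm.locate(iv))

# The suffix array row range [2, 3] covers exactly the suffixes starting
# with 'ana'; locating maps those rows to text offsets 1 and 3 — the two
# places 'ana' occurs in 'banana'.
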