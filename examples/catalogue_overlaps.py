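"""Overlap statistics of a complex catalogue.

Builds a small catalogue in which some complexes share proteins and
prints the overlap-size histogram: how many unordered pairs of complexes
share exactly k proteins, how many pairs overlap at all, and how many
complexes take part in an overlap.
"""

from complexsampler import overlap_histogram

catalogue = [
    {"A", "B"}, {"B", "C"},          # two dimers sharing B
    {"C", "D", "E"},                 # trimer sharing C with a dimer
    {"F", "G", "H", "I"},            # disjoint
    {"H", "I", "J", "K"},            # shares two proteins with the above
]

stats = overlap_histogram(catalogue)
print("overlap-size histogram:", stats.histogram)
print("overlapping pairs:", stats.n_overlapping_pairs)
print("complexes involved in an overlap:", stats.n_complexes_involved)
print()
print("Catalogues like CYC2008 are dominated by overlap size 1; the")
print("histogram keys are intersection sizes, values are pair counts.")
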