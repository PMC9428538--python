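"""Phrase-level similarity basics: Levenshtein distance, LSI, set median.

Builds a handful of phrase strings (sequences of unit labels) and shows
how the similarity index and the set-median exemplar behave.
"""

from whalesong import levenshtein_distance, lsi, set_median

a = ["ascending_moan", "high_squeak", "squeak", "ascending_moan"]
b = ["ascending_moan", "squeak", "squeak", "ascending_moan"]
c = ["descending_cry", "purr", "purr"]

print("edit distance a~b:", levenshtein_distance(a, b))  # one substitution
print("edit distance a~c:", levenshtein_distance(a, c))
print(f"LSI a~b: {lsi(a, b):.3f}   (1 - 1/4: one edit over the longer length)")
print(f"LSI a~c: {lsi(a, c):.3f}   (nothing shared: similarity near zero)")

# the set median is the member most similar to all others (self included):
# the representative version of a theme actually sung by someone
group = [a, b, a, ["ascending_moan", "high_squeak", "squeak"]]
idx, median = set_median(group)
print("set median is input #%d: %s" % (idx, " ".join(median)))
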