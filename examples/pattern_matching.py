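"""Compile disease patterns to a DFA lookup table and match tuples.

Uses the illustrative seven-pattern table over attributes (X, Y, Z),
shows the derived symbol alphabet, matches a few tuples, then
reconfigures the matcher online with an extra pattern.
"""

from wearecg import AttributeRange, Matcher, Pattern, default_disease_patterns, reconfigure

patterns = default_disease_patterns()
matcher = Matcher(patterns)

print("X-axis symbol alphabet:")
for piece in matcher.dmap.pieces["X"]:
    print(f"  {piece.symbol:4s} = {piece.describe()}")
# each symbol is an elementary interval; every pattern range is an exact
# union of symbols, so regex/DFA matching equals numeric range checking.

print(f"\nDFA: {len(matcher.dfa.states)} states, {len(matcher.dfa.alphabet)} symbols")
for values in [(2, 5, 100), (7, 100, 100), (12, 8, 1), (0, 0, 0)]:
    r = matcher.match(values)
    print(f"  {values} -> {list(r.pattern_ids) or 'normal'} {list(r.actions)}")

p8 = Pattern(
    "P8",
    (
        AttributeRange("X", equality=3.0),
        AttributeRange("Y", wildcard=True),
        AttributeRange("Z", wildcard=True),
    ),
    "Disease 5",
)
updated = reconfigure(patterns, add=p8)
print(f"\nafter adding P8 (X = 3): {updated.match((3, 5, 5)).actions}")
# the lookup table is fully regenerated; results for tuples the new
# pattern does not touch are unchanged.
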