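"""The comparison-table arithmetic: detection counts -> summary statistics.

Detection evaluation against a reference observer uses three counts — true
positives (matched), false positives (spurious or misclassified), false
negatives (missed) — and no true negatives, since an object detector never
reports 'correct background'.  The cells below use count triples from a
published drone caribou survey's model-vs-expert comparison.
"""

import mosaicount as mc

# 120 m mosaic, adults: model matched 65 of the expert's adults, added 10
# spurious/misclassified boxes, missed none.
tp, fp, fn = 65, 10, 0
print(f"adults   tp={tp} fp={fp} fn={fn}:"
      f"  accuracy  {mc.round_half_up(mc.accuracy(tp, fp, fn)):.2f}"
      f"  precision {mc.round_half_up(mc.precision(tp, fp)):.2f}"
      f"  recall    {mc.round_half_up(mc.recall(tp, fn)):.2f}")

# same survey, second 120 m mosaic, ghosts — the hard, blurred class
tp, fp, fn = 16, 6, 12
print(f"ghosts   tp={tp} fp={fp} fn={fn}:"
      f"  accuracy  {mc.round_half_up(mc.accuracy(tp, fp, fn)):.2f}"
      f"  precision {mc.round_half_up(mc.precision(tp, fp)):.2f}"
      f"  recall    {mc.round_half_up(mc.recall(tp, fn)):.2f}")

# percentage difference of raw counts: model 114 boxes vs expert 95
d = mc.pct_diff(114, 95, denominator="reference")
print(f"raw counts 114 vs 95: percentage difference "
      f"{mc.round_half_up(d, 1):+.1f}% (model over-counts)")

# of 28 ghosts the expert marked, the model missed 12
print(f"ghost missing proportion: "
      f"{mc.round_half_up(mc.missing_proportion(12, 16)):.2f} "
      f"(= 1 - recall)")

# 9 ghosts were annotated as adults, next to 51 correctly-found adults
print(f"ghost-as-adult misclassification proportion: "
      f"{mc.round_half_up(mc.misclass_proportion(9, 51)):.2f}")
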