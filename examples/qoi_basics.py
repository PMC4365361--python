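"""Quality-of-Information scores for known, unknown, and abducible arguments.

QoI measures how informative a single argument is: 1 when its value is
known, 0 when it is unknown, and 1/Card (disjoint) or 1/(2^Card - 1)
(non-disjoint) when it is restricted to a finite candidate set.
"""

from schizodoc import AbducibleSet, WeightVector, qoi_known, qoi_set, qoi_unknown, score_v

print("known argument:             ", qoi_known())
print("unknown argument:           ", qoi_unknown())
print("2 disjoint candidates:      ", qoi_set(AbducibleSet(2, disjoint=True)))
print("3 overlapping candidates:   ", round(qoi_set(AbducibleSet(3, disjoint=False)), 4))

# the weighted predicate score V over three attributes, equal relevance
w = WeightVector.equal(3)
qois = [qoi_known(), qoi_unknown(), qoi_set(AbducibleSet(2, disjoint=True))]
print("score V (equal weights):    ", round(score_v(w, qois), 4),
      " -- bounded by 1/n =", round(1 / 3, 4))
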