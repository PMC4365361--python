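"""Train the confidence-aware screener and score the 22-year-old patient.

The network (18 inputs -> 8 hidden -> 2 logistic outputs) is trained on a
synthetic population spanning missing rates 0-0.5.  Output 1 is the chance
of schizophrenia; output 2 is the confidence in that answer, trained
against the record's clause DoC, so degraded records earn lower confidence.
"""

import numpy as np

from schizodoc import (
    GeneratorConfig,
    NetworkConfig,
    build_clause,
    clause_to_doc,
    feature_vector,
    generate_population,
    paper_patients,
    predict,
    train,
)
from schizodoc.network import evaluate
from schizodoc.simulate import cases_to_training_data

feats, ys, cs = [], [], []
for k, mr in enumerate((0, 0.1, 0.2, 0.3, 0.4, 0.5)):
    cases = generate_population(GeneratorConfig(n=420, missing_rate=mr,
                                                interval_rate=0.1, seed=100 + k))
    x, y, c = cases_to_training_data(cases)
    feats.append(x), ys.append(y), cs.append(c)
x, y, c = np.vstack(feats), np.concatenate(ys), np.concatenate(cs)
order = np.random.default_rng(1).permutation(len(y))
x, y, c = x[order], y[order], c[order]

model = train(x[:-500], y[:-500], c[:-500], NetworkConfig(seed=1))
metrics = evaluate(model, x[-500:], y[-500:])
print(f"held-out accuracy    {metrics['accuracy']:.3f}  (n={metrics['n']})")
print(f"sensitivity          {metrics['sensitivity']:.3f}")
print(f"specificity          {metrics['specificity']:.3f}")

patient = [r for r in paper_patients() if r.record_id == "male_22"][0]
doc = clause_to_doc(build_clause(patient))
p = predict(model, feature_vector(doc))
print(f"\n22-year-old patient: p(schizophrenia)={p.p_schizophrenia:.2f}  "
      f"confidence={p.confidence:.2f}  (record DoC {doc.clause_doc:.2f})")
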