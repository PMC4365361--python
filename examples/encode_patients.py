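"""Encode the two packaged reference patients into their DoC representation.

Each attribute of the six-column schizophrenia record is widened to a
continuous interval, normalized against its declared domain, and scored
with DoC = sqrt(1 - width^2); the record DoC is the mean of the six.
"""

from schizodoc import build_clause, clause_to_doc, paper_patients

for record in paper_patients():
    doc = clause_to_doc(build_clause(record))
    print(f"{record.record_id} ({record.age}-year-old {record.sex})")
    for a in doc.attributes:
        print(f"  {a.name:<18s} normalized [{a.lo:.4f}, {a.hi:.4f}]  DoC {a.doc:.3f}")
    print(f"  record DoC = {doc.clause_doc:.4f}  (1 = fully known, 0 = fully unknown)")
    print()
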