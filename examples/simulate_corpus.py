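"""Generate a small synthetic corpus of psychiatric-care notes and inspect it.

The generator plants the ground truth: which patients are veterans, which
notes disclose their own service, and which notes carry only confounders
(a family member's service, the Salvation Army, military metaphors).
"""

from msit import SimConfig, generate

corpus = generate(SimConfig(n_patients=20, seed=1))

n_vets = sum(p.self_report for p in corpus.patients)
print(f"{len(corpus.patients)} patients ({n_vets} veterans), "
      f"{len(corpus.documents)} documents\n")

interesting = [a for a in corpus.note_annotations
               if a.contains_self_service or a.contains_other_service][:4]
docs = {d.doc_id: d for d in corpus.documents}
for a in interesting:
    kind = "self-service" if a.contains_self_service else "other-person service"
    print(f"[{a.doc_id}] ({kind})")
    print(f"  {docs[a.doc_id].text[:160]}...\n")

# A veteran is any patient with self_report == 1; the pipeline's job is to
# recover exactly those patients from the note text alone.
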