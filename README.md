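# msit — military-service identification in free-text clinical notes

UK electronic health records carry no universal marker of prior military
service, yet veterans' mental-health needs can only be studied if veterans
can be found. `msit` identifies patients with a history of military service
from free-text psychiatric secondary-care notes using a two-stage design:

1. **Keyword rule stage** — gazetteer phrase matching over normalized text,
   with two guards against the documented failure modes: mentions of
   *another person's* service (a relation word like "father" or "husband"
   within a token window of a military phrase) are removed, and military
   terms contained inside confounder phrases ("Salvation Army") are
   suppressed.
2. **Learned stage** — the four-step preprocessor (strip punctuation; delete
   other-person service mentions; drop stop/frequent words, sparing military
   vocabulary; delete confusion phrases) feeds TF-IDF features
   (idf(t) = ln((1+N)/(1+df(t))) + 1, L2-normalized rows, unigrams+bigrams)
   into a regularized logistic regression. Predicted positives are then
   *gated* by the keyword rule: a positive document with no surviving
   military phrase is flipped to negative.

Document decisions aggregate to patients by logical OR — any positive note
flags the patient as a veteran. The evaluation layer computes the screening
statistics used to validate such a tool against self-reported status:
percent agreement (a+d)/n, PPV/NPV, sensitivity/specificity under two
labeled class conventions, and the Youden index J = sensitivity +
specificity − 1.

Because real case-register text cannot be redistributed, the package ships a
synthetic-note generator (template-based, fully seeded) that plants ground
truth per note and per patient, including the confounders above, so the
whole pipeline is exercisable and testable offline.

## Worked example

```python
from msit import (ConfusionMatrix, format_table, validation_report)

m = ConfusionMatrix(a=111, b=1, c=23, d=11)   # tool × self-report, n=146
print(format_table(m))
r = validation_report(m)                       # study convention
print(f"agreement {r.agreement:.4f}, sens {r.sensitivity:.2f}, "
      f"spec {r.specificity:.2f}, J {r.youden_j:.3f}")
```

prints

```
Outcome           True Non-Veteran  True Veteran  Total
Tool Non-veteran  111               1             112
Tool Veteran      23                11            34
Total             134               12            146
agreement 0.8356, sens 0.83, spec 0.92, J 0.745
```

Agreement says 122 of 146 patients were classified in accordance with their
self-report. Under the study convention, sensitivity 0.83 is the proportion
of true non-veterans the tool called non-veteran, and specificity 0.92 the
proportion of true veterans it recovered; J = 0.745 summarizes both and is
deliberately reported as a separate number from agreement.

Longer narrative examples live in `examples/` (one script per capability:
simulation, rule classification, the full train/evaluate pipeline, screening
statistics, eligibility flow). A thin CLI wraps the same functions:

```
msit simulate --out work --seed 42 --n-patients 400
msit train    --docs work/documents.jsonl --labels work/doc_labels.csv --out work/model.joblib
msit predict  --docs work/documents.jsonl --engine ml+post --model work/model.joblib --out work/decisions.csv
msit aggregate --decisions work/decisions.csv --docs work/documents.jsonl --out work/predictions.csv
msit evaluate --pred work/predictions.csv --truth work/truth.csv --out work/report.json
msit flow     --metadata work/metadata.csv
```

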