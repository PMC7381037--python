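"""Look inside a fitted model: top terms per topic and fold-in inference.

Trains a small model, prints each topic's most probable diagnoses and
medications (the two coupled views), then infers the topic proportions of a
held-out prescription one view at a time.
"""

from rxscreen import (
    Hyperparams,
    PrescriptionRecord,
    SyntheticSpec,
    generate_corpus,
    infer_record,
    train,
)

spec = SyntheticSpec(M=2000, K_true=5, V_A=50, V_B=50, seed=11)
corpus, _ = generate_corpus(spec)
model = train(corpus, Hyperparams(K=5), n_iter=300, seed=11)

for k in range(model.K):
    top_dx = model.phi_A[k].argsort()[::-1][:3]
    top_rx = model.phi_B[k].argsort()[::-1][:3]
    dx = ", ".join(f"{model.vocab_A.term(v)} ({model.phi_A[k, v]:.2f})" for v in top_dx)
    rx = ", ".join(f"{model.vocab_B.term(v)} ({model.phi_B[k, v]:.2f})" for v in top_rx)
    print(f"topic {k}:  dx: {dx}  |  rx: {rx}")
print(
    "Meaning: each topic couples a cluster of diagnoses with the medications "
    "prescribed for them; the numbers are topic-term probabilities."
)

record = PrescriptionRecord(
    "held-out", diagnoses=[model.vocab_A.term(0)], medications=[model.vocab_B.term(0)]
)
est = infer_record(model, record, seed=0)
print(f"\nheld-out prescription {record.diagnoses} / {record.medications}")
print("theta from diagnoses:  ", est.theta_A.round(3))
print("theta from medications:", est.theta_B.round(3))
print(
    "Meaning: the two views are inferred separately; when the prescription "
    "is appropriate they point to the same topic."
)
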