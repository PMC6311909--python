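"""Train, fold in held-out proteins, and score the predictions.

Prediction freezes the trained label-topic and topic-word parameters
and resamples only each new protein's label counts; every label (plus
the background) is admissible.  The evaluation reports the six
standard multi-label criteria.
"""

import logging

import numpy as np

from pftp import (
    Hyperparameters,
    SamplingSchedule,
    binarize,
    evaluate,
    predict,
    sample_corpus,
    sample_model,
    train,
)

logging.getLogger("pftp").setLevel(logging.ERROR)

hyper = Hyperparameters(alpha=0.5, beta=0.5, lam=0.1)
true_model = sample_model(L=4, m=2, B=1, W=60, hyper=hyper, seed=21)
train_set = sample_corpus(true_model, D=150, labels_per_doc=2,
                          tokens_per_doc=120, seed=22)
held_out = sample_corpus(true_model, D=50, labels_per_doc=2,
                         tokens_per_doc=120, seed=23)

result = train(train_set.corpus, train_set.labels, true_model.partition,
               hyper, SamplingSchedule(500, 250, 50, seed=24))
pred = predict(held_out.corpus, result.estimate,
               SamplingSchedule(500, 250, 50, seed=25),
               true_model.label_space.labels)

L = true_model.label_space.n_labels
truth = [set(map(int, np.flatnonzero(held_out.labels.rows[d][:L])))
         for d in range(held_out.corpus.n_docs)]
label_index = {lab: j for j, lab in enumerate(pred.label_ids)}
predicted = [{label_index[lab] for lab in s} for s in binarize(pred)]
report = evaluate(truth, pred.scores, predicted=predicted)

print("first held-out protein:")
print("  true labels:", sorted(truth[0]))
print("  scores:", np.round(pred.scores[0], 3).tolist(),
      " background mass:", round(float(pred.background[0]), 3))
print("\nsix-criterion report (HL/One-Error lower is better, rest higher):")
for key, value in report.to_dict().items():
    print(f"  {key}: {value:.4f}" if value is not None else key)
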