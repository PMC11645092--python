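"""Which stimulus categories drive correct ASD classification?

Trains on a mixed corpus where only "people" images carry class signal, then
computes pairwise TracIn influence of every training sample on the correctly
classified ASD test samples and aggregates by stimulus category.  The
"people" category should dominate — the synthetic analogue of attribution
recovering that social stimuli are what separates the groups.
"""

import numpy as np

from gazeattr import (
    SyntheticSpec,
    aggregate_influence_by_category,
    build_dataset,
    build_model,
    desk_config,
    influence_table,
    prepare_records,
    split_dataset,
    train,
)
from gazeattr.model import slice_batch
from gazeattr.nn import sigmoid
from gazeattr.train import forward_in_batches

spec = SyntheticSpec(seed=1)
records, truth = build_dataset(spec)
config = desk_config()

train_recs, val_recs, test_recs = split_dataset(records, seed=1)
prep_train = prepare_records(train_recs, config)
prep_test = prepare_records(test_recs, config)
model = build_model(config, seed=1)
checkpoints, _ = train(model, prep_train, config, seed=1, val_records=prepare_records(val_recs, config))

proba = sigmoid(forward_in_batches(model, prep_test, config.batch_size))
targets_idx = np.where((prep_test["labels"] == 1) & (proba >= 0.5))[0]
print(f"{targets_idx.size} correctly classified ASD test samples")

table = influence_table(checkpoints, model, prep_train, slice_batch(prep_test, targets_idx))
ranked = aggregate_influence_by_category(table, truth["categories"])
print(ranked.to_string(index=False))
# mean_positive_influence: average positive TracIn influence of the
# category's training samples on the target test samples; the top row is the
# category whose training examples most supported correct ASD classification
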