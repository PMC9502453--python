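"""Desk-scale training configuration for the parameter-recovery runs.

One frozen configuration, shared by the signal and adversarial pipelines:
L1 weight decay supplies the sparsity prior the high-dimensional synthetic
regime needs (see docs/methods.md), and the epoch budget is the smallest
that reliably clears the recovery margin on one CPU.
"""

from ms2fp.neural import Hyperparameters

RECOVERY_HP = Hyperparameters(
    n_neurons=200,
    n_task_specific=200,
    learning_rate=4e-3,
    activation="relu",
    dropout=0.0,
    batch_size=32,
    patience=60,
    optimizer="adam",
    max_epochs=300,
    weight_decay=0.3,
    weight_decay_kind="l1",
)
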