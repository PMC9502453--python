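# Desk-scale configuration: the default synthetic dataset; the full
# pipeline (5 training replicates) takes on the order of ten minutes on
# one CPU.  Generalisation to held-out compounds needs a few hundred
# training compounds — much smaller runs will memorise instead.
synth:
  n_compounds: 300
  seed: 7

grid: {}          # defaults: 45.0-704.5 Da, 0.1 Da resolution

curation: {}      # default thresholds and vocabularies

dimred:
  n_components: 50
  penalty: 0.0

hyperparameters:
  n_neurons: 200
  n_task_specific: 200
  learning_rate: 0.004
  activation: relu
  dropout: 0.0
  batch_size: 32
  patience: 60
  optimizer: adam
  max_epochs: 300
  weight_decay: 0.3
  weight_decay_kind: l1
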