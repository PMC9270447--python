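# Default hyperparameter grids per model family.
#
# Tuning is an exhaustive grid search with chronological expanding-window
# cross-validation; ties are broken toward the simpler model (fewer/smaller
# trees or layers, larger penalty).  Override any family by passing a grid
# mapping to tune_hyperparameters / run_suite, or via the `grids:` section of
# a run config file.
RV:            # ridge regression — penalty coefficient
  alpha: [0.01, 0.1, 1.0, 10.0, 100.0]
RF:            # random forest — number of trees, tree depth (null = unlimited)
  n_estimators: [50, 150]
  max_depth: [4, 8, null]
XG:            # gradient boosting — penalty, number of trees, tree depth
  reg_lambda: [0.1, 1.0, 10.0]
  n_estimators: [50, 150]
  max_depth: [2, 4, 6]
NN:            # multilayer perceptron — penalty, hidden-layer layout, activation
  alpha: [0.0001, 0.01, 1.0]
  hidden_layer_sizes: [[32], [64], [32, 32]]
  activation: [relu, tanh]
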