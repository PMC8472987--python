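# Default pipeline configuration.
# Printed study settings are kept verbatim where the method states them;
# the remaining values are package design choices (see docs/methods.md).

# --- synthetic cohort ---
n_subjects: 40
class_balance: 0.5        # equal class proportions
qt_effect: 1.08           # hyperglycemia QT timing prolongation (generator parameter)
pr_effect: 1.05           # hyperglycemia PR timing prolongation (generator parameter)
duration_s: 60.0          # 60-s single-lead recordings
sampling_rate_hz: 1000.0  # 1000 Hz acquisition
mean_hr_bpm: 70.0

# --- preprocessing ---
trim_seconds: 10.0        # discard first/last 10 s
low_hz: 1.0               # Butterworth band-pass 1-40 Hz, order 4
high_hz: 40.0
filter_order: 4

# --- segmentation ---
pre_ms: 200.0             # 600-sample beat window at 1000 Hz
post_ms: 400.0

# --- features ---
apply_qtc: true           # Framingham correction of the QT time axis
outlier_scope: all        # IQR fences fitted before the split (replication order)
standardizer_scope: train

# --- model ---
model: dnn                # dnn | logistic | svm-linear | svm-poly | svm-rbf
dnn:
  n_hidden_layers: 9      # 9 x 500 hidden units + 1 sigmoid output
  hidden_units: 500
  learning_rate: 1.0e-4   # SGD; halved after 20 epochs without improvement
  lr_halving_patience: 20
  early_stop_patience: 100
  max_epochs: 1000
  batch_size: 32
  validation_fraction: 0.1
  seed: 0

# --- evaluation ---
threshold: 0.5
train_fraction: 0.8

seed: 0
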