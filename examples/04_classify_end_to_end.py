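"""Full pipeline on a small synthetic study: segment, extract features,
train both classifiers on an 80/20 stratified split, and report the seven
evaluation metrics for the held-out images.
"""

import numpy as np
import pandas as pd

from dermoscan import (
    AnnConfig,
    LabeledDataset,
    SvmConfig,
    adaptive_snake,
    compute_metrics,
    confusion_matrix,
    extract_feature_vector,
    generate_dataset,
    predict,
    preprocess_pipeline,
    split_dataset,
    train_ann,
    train_svm,
)

samples = generate_dataset(n_benign=24, n_malignant=12, seed=5)
rows, labels = [], []
for s in samples:
    gray = preprocess_pipeline(s.image)
    mask = adaptive_snake(gray).mask
    rows.append(extract_feature_vector(s.image, gray, mask))
    labels.append(s.spec.label)

data = LabeledDataset(X=pd.DataFrame(rows), y=np.array(labels))
train, test = split_dataset(data, train_fraction=0.8, seed=5)
print(f"{len(train)} training / {len(test)} held-out samples")

for name, fit, cfg in (("ANN", train_ann, AnnConfig(seed=5)), ("SVM", train_svm, SvmConfig(seed=5))):
    model = fit(train, cfg)
    preds = predict(model, test.X)
    cm = confusion_matrix(test.y, preds, positive_class="malignant")
    m = compute_metrics(cm)
    print(
        f"{name}: accuracy {m.accuracy:.2f}, precision {m.precision}, "
        f"sensitivity {m.sensitivity}, specificity {m.specificity}, "
        f"F1 {m.f1}, Jaccard {m.jaccard}, MCC {m.mcc}"
    )
# "malignant" is the positive class; sensitivity is the fraction of melanoma-
# like lesions caught, specificity the fraction of nevi correctly cleared.
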