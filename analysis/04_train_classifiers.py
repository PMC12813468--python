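"""Train the CNN and FCN per feature and tabulate test metrics.

For each feature's heatmap dataset (results/heatmaps/<feature>/):
subject-level stratified 80:20 split, CNN trained 70 epochs and FCN 50
epochs (Adam, lr 0.001, batch 32), then confusion-matrix metrics on
the held-out subjects.  Writes results/classification_metrics.csv and
the trained weights under results/models/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from trajheat import classifiers as clf
from trajheat import evaluation as ev

FEATURES = ("gm_pct", "wm_pct", "csf_pct", "ct_mm", "wmh_pct")


def run_one(feature: str, arch: str, heatmap_dir: Path, model_out: Path, seed: int):
    d = heatmap_dir / feature
    X = np.load(d / "heatmaps.npy")
    y = np.load(d / "labels.npy")
    epochs = clf.CNN_EPOCHS if arch == "cnn" else clf.FCN_EPOCHS
    cfg = clf.TrainConfig(epochs=epochs, seed=seed)
    tr, te = clf.stratified_split(y, cfg.test_fraction, seed)
    model = clf.build_cnn(seed=seed) if arch == "cnn" else clf.build_fcn(seed=seed)
    trained = clf.train_model(model, X[tr], y[tr], cfg, arch=arch, feature_name=feature)

    from trajheat.nn import softmax_cross_entropy
    logits = trained.model.forward(clf.prepare_inputs(X[te]))
    test_loss, _ = softmax_cross_entropy(logits, y[te])
    y_pred = clf.predict_labels(trained, X[te])
    rep = ev.metrics(ev.confusion(y[te], y_pred), loss=test_loss)

    mdir = model_out / f"{arch}_{feature}"
    mdir.mkdir(parents=True, exist_ok=True)
    np.savez(mdir / "weights.npz",
             **{f"p{i}": p for i, p in enumerate(trained.model.params)})
    (mdir / "history.json").write_text(json.dumps({
        "arch": arch, "feature": feature, "seed": seed,
        "test_indices": te.tolist(), "history": trained.history}))
    return {
        "feature": feature, "arch": arch.upper(),
        "accuracy": rep.accuracy, "precision": rep.precision_weighted,
        "recall": rep.recall_weighted, "f1": rep.f1_weighted,
        "loss": test_loss, "n_test": len(te),
    }


def main(heatmap_dir: Path = Path("results/heatmaps"),
         out: Path = Path("results"), seed: int = 0) -> None:
    rows = []
    for feature in FEATURES:
        for arch in ("cnn", "fcn"):
            row = run_one(feature, arch, heatmap_dir, out / "models", seed)
            rows.append(row)
            print(f"{feature:8s} {arch.upper():3s} "
                  f"acc {row['accuracy']:.3f}  P {row['precision']:.3f}  "
                  f"R {row['recall']:.3f}  F1 {row['f1']:.3f}  loss {row['loss']:.3f}")
    df = pd.DataFrame(rows)
    df.to_csv(out / "classification_metrics.csv", index=False)
    best = df.loc[df.accuracy.idxmax()]
    print(f"\nbest feature x architecture: {best.feature} / {best.arch} "
          f"(accuracy {best.accuracy:.3f} on {best.n_test} held-out subjects)")
    print(f"wrote {out / 'classification_metrics.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--heatmaps", type=Path, default=Path("results/heatmaps"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    a = ap.parse_args()
    main(a.heatmaps, a.out, a.seed)
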