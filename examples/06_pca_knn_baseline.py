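"""PCA + KNN ablation: project concat-layer features onto the leading
eigenvectors and classify with nearest neighbours, sweeping the retained
eigenvector count (lambda) by cross-validation on the training features.
"""
import numpy as np

from drenet import KNNConfig, lambda_sweep, pca_fit, pca_project

# synthetic features whose class structure lives in a 4-d subspace
rng = np.random.default_rng(0)
basis = rng.normal(size=(4, 256))
feats, labels = [], []
for i in range(4):
    z = rng.normal(size=(30, 4)) * 0.4 + rng.normal(size=4) * 5
    feats.append(z @ basis + rng.normal(0, 0.2, (30, 256)))
    labels += [f"C{i+1}"] * 30
feats = np.vstack(feats)

curve, best = lambda_sweep(feats, labels, range(1, 16), folds=5, seed=0,
                           config=KNNConfig(k=1))
for lam in (1, 2, 4, best, 15):
    print(f"lambda={lam:2d}: CV accuracy {curve[lam]:.3f}")
print(f"\nbest lambda = {best} — accuracy plateaus once the informative "
      "subspace is covered.")
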