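"""Clustering latent posteriors with the cross-entropy pseudometric (CRSD).

Builds a fixture where the two groups share the same mean location and
differ only in posterior spread - invisible to clustering on means, visible
to CRSD, which compares whole distributions through reference densities.
"""

import numpy as np

from cytovae import (
    ReferenceSet,
    agglomerative_crsd,
    baseline_cluster,
    clustering_metrics,
    crsd_matrix,
    generate_latent_fixture,
)

posteriors, truth = generate_latent_fixture(
    n=60, dim=8,
    component_means=[np.zeros(8), np.zeros(8)],
    component_stddevs=[np.full(8, 0.3), np.full(8, 1.5)],
    assignment=np.repeat([0, 1], 30), seed=0,
)

refs = ReferenceSet.from_posteriors(posteriors)
matrix = crsd_matrix(posteriors, refs)
agg_sm = agglomerative_crsd(matrix, n_clusters=2)
h, c, v = clustering_metrics(truth, agg_sm.labels)
print(f"Agg-SM (CRSD):      h={h:.3f} c={c:.3f} V={v:.3f}")

means = np.array([p.mean for p in posteriors])
agg_em = baseline_cluster(means, "agglomerative-euclidean", n_clusters=2)
h, c, v = clustering_metrics(truth, agg_em.labels)
print(f"Agg-EM (Euclidean): h={h:.3f} c={c:.3f} V={v:.3f}")
print("Both groups sit at the origin in mean-space, so Euclidean clustering "
      "is near chance; CRSD reads the per-point uncertainty and separates "
      "them (h/c/V near 1).")
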