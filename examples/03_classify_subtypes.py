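"""Nearest-centroid subtype classification and variant concordance.

Fits k-means centroids (k=4) on a well-separated synthetic training cohort,
classifies by nearest centroid in z-space, and compares the fasting-glucose
variant against the glycemia-free variant (which drops the glucose feature
entirely).
"""

from diatraj import concordance, fit_centroids
from diatraj.classify import classify_cohort, separated_feature_cohort

features = separated_feature_cohort(n_per_subtype=30, separation=6.0, noise_sd=1.0, seed=3)

labels = {}
for variant in ("fpg", "glycemia_free"):
    centroids = fit_centroids(features, variant=variant, seed=0)
    assigned = classify_cohort(features, centroids)
    labels[variant] = assigned["subtype"]
    accuracy = 100.0 * (assigned["subtype"].to_numpy() == features["true_subtype"].to_numpy()).mean()
    print(f"{variant:14s}: accuracy vs generator labels = {accuracy:.1f}%")

pct, confusion = concordance(labels["fpg"], labels["glycemia_free"])
print(f"\nconcordance between variants: {pct}%")
print(confusion.to_string())
print(
    "\nAgreement between variants measures how much the glycemia feature "
    "changes assignments; on well-separated clusters both variants recover "
    "the generating labels, so they agree fully."
)
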