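"""Classify a synthetic corpus end to end: exemplars -> keywords -> soft cosine.

Generates a seeded corpus of 5 categories x 100 documents whose tokens mix a
category-specific vocabulary (90%) with a shared pool (10%), builds the
per-category reference keyword lists from exemplar texts, scores every
document by soft cosine against each category's keyword text using toy
embeddings that cluster by category, and gates each assignment with the
t-test rule at alpha = 0.05.
"""

import numpy as np

import litsim as ls

bundle = ls.generate(ls.CorpusSpec(n_categories=5, docs_per_category=100,
                                   mixing=0.9, seed=42))
ref = ls.build_reference(bundle.exemplars, first_k=200, budget=100, ngram_max=1)
print("reference keyword list sizes:",
      {kl.category: len(kl.entries) for kl in ref.lists})

decisions = ls.classify_corpus(bundle.documents, ref, "similarity",
                               bundle.embeddings, alpha=0.05)
scored = [d for d in decisions if d.assigned != ls.ETC]
accuracy = np.mean([d.assigned == bundle.truth[d.record_id] for d in scored])
print(f"{len(decisions)} records; {len(decisions) - len(scored)} abstained to ETC")
print(f"accuracy on non-abstained records: {100 * accuracy:.1f}%")
print()
print("With well-separated vocabularies nearly every record is confidently "
      "assigned its generating category; lowering `mixing` blurs the "
      "categories and pushes records into ETC or across category lines.")
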