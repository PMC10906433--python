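"""Extract ranked keywords from a short exemplar text.

The extractor is unsupervised and uses only within-text statistics: term
frequency (normalized by the corpus-free mean and spread of frequencies),
sentence position, casing, dispersion across sentences, and the diversity of
left/right co-occurring terms.  Lower score = more relevant.
"""

import litsim as ls

TEXT = (
    "Aneurysm clipping remains the standard treatment for many ruptured "
    "aneurysms. Aneurysm coiling is an endovascular alternative with lower "
    "operative morbidity. Subarachnoid hemorrhage follows aneurysm rupture "
    "and drives outcome. Vasospasm after subarachnoid hemorrhage worsens "
    "ischemic injury."
)

kl = ls.extract_keywords(TEXT, max_k=8, ngram_max=2, category="Vascular")
print(f"top keywords for category {kl.category!r}:")
for kw, score in kl.entries:
    print(f"  {score:7.4f}  {kw}")
print()
print("Phrases like 'subarachnoid hemorrhage' outrank generic single terms "
      "because their component terms are frequent, well dispersed, and occur "
      "in diverse contexts; the scores feed the dedup/truncation pipeline "
      "that builds the per-category reference lists.")
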