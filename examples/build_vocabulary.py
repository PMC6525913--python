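"""Build the controlled topic vocabulary: expert seed list, index-term
enrichment, and embedding-proposed synonyms gated by review.

The synthetic corpus plants the pair (consolidation, reconsolidation) in
matched sentence contexts, so the embedding proposes it; the reviewer
then accepts it into the vocabulary.
"""

from conceptlink import (CorpusSpec, EmbeddingConfig, apply_review,
                         enrich_from_index_terms, generate_corpus,
                         load_seed_vocabulary, propose_synonyms,
                         train_embedding)

vocab = load_seed_vocabulary()  # packaged expert list
print(f"expert seed terms: {len(vocab)}")

spec = CorpusSpec(
    concepts=["neuroplasticity", "stroke recovery", "learning"],
    n_records_per_concept={c: 400 for c in
                           ("neuroplasticity", "stroke recovery", "learning")},
    topic_frequency={("consolidation", "learning"): 0.0},
    synonym_pairs=[("consolidation", "reconsolidation")],
    seed=2)
corpora, _ = generate_corpus(spec)

vocab = enrich_from_index_terms(vocab, corpora, min_doc_count=5)
print(f"after index-term enrichment: {len(vocab)} terms "
      f"(version {vocab.version})")

model = train_embedding(corpora, EmbeddingConfig(seed=2))
candidates = propose_synonyms(model, vocab, k=10, min_similarity=0.6)
print(f"synonym candidates above cosine 0.6: {len(candidates)}")
for c in candidates[:5]:
    print(f"  {c.seed_surface!r} -> {c.candidate_surface!r} "
          f"(cosine {c.similarity:.3f})")

decisions = {c.candidate_surface: "accept" for c in candidates
             if c.candidate_surface == "reconsolidation"}
vocab = apply_review(vocab, candidates, decisions)
term = vocab.get("reconsolidation")
print(f"accepted: {term.surface!r} origin={term.origin}")
print("(only reviewed candidates become matchable vocabulary terms)")
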