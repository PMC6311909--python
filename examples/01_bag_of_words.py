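"""Turn protein sequences into the model's bag-of-words input.

A protein sequence is read as a text string over the 20-residue
alphabet; its words are overlapping length-k blocks (k-mers).  The
corpus becomes a protein x block count matrix.
"""

from pftp import build_bow, build_vocabulary, tokenize_protein

sequences = {
    "P1": "MSTSMSHR",
    "P2": "TSTSKWQ",
    "P3": "MSMSMS",
}

tokenized = [tokenize_protein(pid, seq, k=2) for pid, seq in sequences.items()]
for doc in tokenized:
    print(f"{doc.protein_id}: {' '.join(doc.blocks)}")

vocab = build_vocabulary(tokenized)
corpus = build_bow(tokenized, vocab)
print(f"\nvocabulary ({vocab.size} blocks): {' '.join(vocab.blocks)}")
print("\ncount matrix (rows = proteins, columns = blocks):")
for pid, row in zip(corpus.doc_ids, corpus.counts):
    print(pid, row.tolist())
print(f"\ntokens per protein N_d: {corpus.doc_totals.tolist()}")
print("Each row is one protein's word counts; e.g. 'MS' occurs "
      f"{corpus.counts[2, vocab.index('MS')]} times in P3.")
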