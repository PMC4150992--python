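"""Dirichlet-smoothed query-likelihood scoring over an inverted index.

Indexes three tiny documents, scores a query by
score(D,Q) = sum_i ln((tf_{qi,D} + mu*tf_{qi,C}/|C|) / (|D|+mu)),
and shows that smoothing gives finite scores even when a query term is
missing from a document (it borrows probability mass from the collection).
"""

import math

from litgo.retrieval import DirichletParams, build_index, dirichlet_score, search
from litgo.textfeat import load_stopwords, tokenize_stem

docs = {
    "P1": "the phosphatase localizes to the central spindle",
    "P2": "kinase activity regulates the spindle checkpoint",
    "P3": "embryonic development requires maternal transcripts",
}
index = build_index(docs)
print(f"indexed {len(docs)} docs, {index.collection_len} tokens, "
      f"{len(index.postings)} distinct stems")

stoplist = load_stopwords()
query = [t for t in tokenize_stem("phosphatase localizes to spindle") if t not in stoplist]
print(f"query stems: {query}")

params = DirichletParams(mu=10.0)
for doc_id in sorted(docs):
    score = dirichlet_score(query, doc_id, index, params)
    print(f"  score({doc_id}) = {score:.4f}"
          + ("   <- mentions no query stem, smoothed mass only" if doc_id == "P3" else ""))

ranked = search(query, index, top_k=3, params=params)
print("ranking:", " > ".join(sd.doc_id for sd in ranked))

# the single-term case is hand-checkable: one doc "a b a", mu=2, query "a"
tiny = build_index({"d": "a b a"})
s = dirichlet_score(["a"], "d", tiny, DirichletParams(mu=2.0))
print(f"\nhand check: ln((2 + 2*(2/3))/(3+2)) = ln(10/15) = {math.log(10/15):.4f}, "
      f"scorer gives {s:.4f}")
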