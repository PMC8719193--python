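"""Cluster a vocabulary of one-word quotations via CBOW embeddings.

Generates a topic-structured corpus (three planted semantic groups), trains
CBOW word vectors on it, scans k-means cluster counts 2..10, and lets a
purity-based labeler pick the first silhouette-ranked k with at least one
homogeneous cluster — the automatic stand-in for the human labelling loop.
"""

from quotedtext import NoteConfig, generate_topic_corpus, train_cbow
from quotedtext.clustering import cluster_purity, make_purity_labeler, scan_k, select_solution
from quotedtext.embeddings import map_vocabulary

corpus, topic_map = generate_topic_corpus(NoteConfig(seed=31), n_sentences=3000)
print(f"corpus: {len(corpus)} sentences, {len(topic_map)} words in {len(set(topic_map.values()))} topics")

vectors = train_cbow(corpus, dimension=50, window=5, min_count=5, epochs=3, seed=32)
matrix, words, oov = map_vocabulary(sorted(topic_map), vectors)
print(f"embedded {len(words)} words ({len(oov)} out of vocabulary)\n")

scan = scan_k(matrix, k_min=2, k_max=10, restarts=10, seed=33, words=words)
print(scan.table.round(4).to_string(index=False))

outcome = select_solution(scan, {w: 1 for w in words}, make_purity_labeler(topic_map))
sol = outcome.chosen
print(f"\nselected k = {sol.k} (mean silhouette {sol.mean_silhouette:.3f}); "
      f"purity vs planted topics = {cluster_purity(sol.assignments, topic_map):.2f}")
for cluster in outcome.report.clusters:
    print(f"  cluster {cluster['cluster_id']} [{cluster['label']}]: {', '.join(cluster['top_words'][:6])} ...")
# The silhouette maximum falls at the planted topic count and each cluster's
# most frequent words share one topic, so the labeler accepts the first k.
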