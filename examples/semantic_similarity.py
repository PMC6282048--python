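"""Disease semantic similarity from ontology DAGs.

Two diseases that share part of their ancestor chain in a MeSH-style
hierarchy are semantically similar: every shared ancestor contributes to
both diseases, with a contribution that halves per level of separation.
"""

from llcmda import DiseaseDAG, contributions, semantic_similarity, semantic_value

# Disease A sits two levels below the shared term "cancer":
#   A -> carcinoma -> cancer ; B -> sarcoma -> cancer
dag_a = DiseaseDAG(
    "A", nodes={"A", "carcinoma", "cancer"},
    edges={("A", "carcinoma"), ("carcinoma", "cancer")},
)
dag_b = DiseaseDAG(
    "B", nodes={"B", "sarcoma", "cancer"},
    edges={("B", "sarcoma"), ("sarcoma", "cancer")},
)

cm = contributions(dag_a)
print("contributions of A's terms:", dict(sorted(cm.contributions.items())))
print("semantic value DV(A):", semantic_value(cm))
print("similarity S(A, B):", round(semantic_similarity(dag_a, dag_b), 4))

# The only shared term is "cancer" (0.25 from each side) against a total
# semantic mass of 1.75 + 1.75, giving 0.5 / 3.5 ~ 0.1429. Sharing the
# deeper "carcinoma" term as well would raise the similarity:
dag_b2 = DiseaseDAG(
    "B", nodes={"B", "carcinoma", "cancer"},
    edges={("B", "carcinoma"), ("carcinoma", "cancer")},
)
print("similarity when the parent is shared too:",
      round(semantic_similarity(dag_a, dag_b2), 4))
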