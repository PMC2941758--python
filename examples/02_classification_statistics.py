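"""The five-class hypergeometric labelling on worked EST counts.

Each entity (gene or intron) is tested in one tissue with two one-sided
exact hypergeometric tests against the tissue's pooled library sizes;
the significant direction assigns the label, exclusivity upgrades it to
a double letter (TT/NN).
"""

from estsplice import classify_entity, heterogeneity_summary
from estsplice.classify import ClassificationResult
from estsplice.model import TissueBackground
from estsplice.reference import intron_concordance

bg = TissueBackground("CNS", n_normal=50_000, n_tumor=50_000)
for k_tumor, k_normal in [(30, 0), (29, 1), (5, 5), (3, 27)]:
    r = classify_entity("demo", k_tumor, k_normal, bg, m_tests=100)
    print(f"k_tumor={k_tumor:>2} k_normal={k_normal:>2}  "
          f"p_tumor={r.p_tumor:.3g}  p_normal={r.p_normal:.3g}  "
          f"label={r.label:<2} (Bonferroni m=100: {r.label_bonferroni})")
print("-> TT/NN mean exclusive expression, T/N over-expression, "
      "E no significant difference\n")

# cross-tissue concordance of the reference screen's intron labels
s = intron_concordance()
print(f"introns labelled in >= 5 tissues: {s.n_total}")
print(f"  heterogeneous (both directions): {s.n_heterogeneous} "
      f"({s.pct_heterogeneous}%)")
print(f"  homogeneously tumoral: {s.n_homogeneous_tumor} "
      f"({s.pct_homogeneous_tumor}%)")
print(f"  homogeneously normal: {s.n_homogeneous_normal} "
      f"({s.pct_homogeneous_normal}%)")
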