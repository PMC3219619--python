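"""Individual choice rules: how social and private evidence set the odds.

Evaluates the core sigmoid follow rule and its variants (asymmetric sites,
modified replicas, distinct fish/replica reliabilities, many options) at a
few illustrative states and prints the resulting choice probabilities.
"""

from shoalbayes import (
    choice_prob_asymmetric,
    choice_prob_multi,
    choice_prob_two_replicas,
    follow_prob_symmetric,
    reliability_from_rates,
)

s = 2.5  # conspecific reliability: correct choices 2.5x likelier than mistakes
print(f"reliability s = {s} (e.g. P(correct)=0.625 / P(mistake)=0.25 -> "
      f"{reliability_from_rates(0.625, 0.25):.2f})")

print("\nSymmetric two-choice follow rule, P(go to x) vs Dn = n_x - n_y:")
for dn in range(-3, 4):
    print(f"  Dn = {dn:+d}:  P = {follow_prob_symmetric(s, dn):.4f}")
print("A lead of one conspecific already sways the decision to "
      f"{follow_prob_symmetric(s, 1):.3f}; the sigmoid steepens with s.")

print("\nAsymmetric sites (private evidence a = 3 for x):")
for dn in (-2, 0, 2):
    print(f"  Dn = {dn:+d}:  P = {choice_prob_asymmetric(3.0, s, dn):.4f}")

rho = 0.35  # less-/more-attractive replica reliability ratio
print(f"\nTwo modified replicas (attractive one at x, ratio rho = {rho}):")
print(f"  no fish yet:    P = {choice_prob_two_replicas(s, rho, 0):.4f}")
print(f"  one fish at y:  P = {choice_prob_two_replicas(s, rho, -1):.4f}")

print("\nThree options, one individual already at the first:")
p = choice_prob_multi(s, [1, 0, 0])
print("  P =", [round(float(v), 4) for v in p],
      " (sums to", round(float(p.sum()), 10), ")")
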