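"""Generate a synthetic two-class decision table with known attribute roles.

Builds the 569-sample, 30-attribute table whose structure mirrors a
diagnostic cytology dataset (10 informative base features, each with two
correlated redundant companions), and a small table with pure-noise
attributes.  The printed roles are the ground truth a reduction method is
later judged against.
"""

from roughpnn import SyntheticSpec, generate, wbcd_like_spec

table, roles = generate(wbcd_like_spec(seed=7))
print(f"wbcd-like table: {table.n_samples} samples x {table.n_attributes} attributes")
print(f"class counts:    {table.class_counts()}")
print(f"roles:           {sum(r == 'informative' for r in roles.values())} informative, "
      f"{sum(r == 'redundant' for r in roles.values())} redundant")

spec = SyntheticSpec(n_per_class={"benign": 60, "malignant": 40}, seed=0)
small, small_roles = generate(spec)
noise = sorted(a for a, r in small_roles.items() if r == "noise")
print(f"\nsmall table:     {small.n_samples} samples x {small.n_attributes} attributes")
print(f"noise attributes (class-independent): {noise}")
print("A good attribute reduction should select none of the noise attributes.")
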