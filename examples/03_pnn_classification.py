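"""Train and evaluate the probabilistic neural network on a reduced table.

Runs the full pipeline on the wbcd-like synthetic table with the reference
protocol: a stratified 400/169 split (250/150 training per class),
reduction at xi = 0.25, PNN smoothing factor (SPREAD) 0.75.  Prints the
confusion counts, accuracy / precision / recall with benign as the
positive class, and a 95% Wilson interval for the accuracy.
"""

from roughpnn import evaluate, generate, wbcd_like_spec

table, _ = generate(wbcd_like_spec(seed=7))
res = evaluate(
    table,
    train_counts={"benign": 250, "malignant": 150},
    seed=1,
    xi=0.25,
    radius_delta=0.15,
    sigma=0.75,
)

print(f"reduct: {len(res['reduct'].selected_B)} attributes "
      f"{list(res['reduct'].selected_B)}")
for split in ("train", "test"):
    rep = res[split]
    c = rep.counts
    print(f"\n{split} set (n={c.n}, positive = benign)")
    print(f"  counts: tp={c.tp} fp={c.fp} fn={c.fn} tn={c.tn}")
    print(f"  accuracy  {100 * rep.accuracy:.2f}%  "
          f"(95% CI [{rep.ci_low:.4f}, {rep.ci_high:.4f}])")
    print(f"  precision {100 * rep.precision:.2f}%   recall {100 * rep.recall:.2f}%")
print("\nPrecision counts how many benign calls were right; recall how many "
      "benign samples were found. Misclassifying malignant as benign lowers "
      "precision here.")
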