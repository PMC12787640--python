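# mambaseg

Breast-ultrasound lesion segmentation with a Mamba–CNN hybrid network —
a visual state-space (VSS) encoder, a hybrid channel/spatial attention
module at the bottleneck (HAEM), cross-attention feature fusion on every
skip connection (CFM), and a transposed-convolution decoder — plus the
compound loss, the standard metric suite (Dice, HD95, Precision, Recall),
and a seeded synthetic-phantom generator so the whole pipeline trains and
evaluates on one CPU with no data download.

Breast ultrasound is hard to segment automatically: speckle noise,
acoustic shadows and blurred lesion boundaries defeat purely local
(convolutional) models, while full self-attention is quadratic in image
size.  Selective state-space models offer linear-time global context: each
channel of a token sequence passes through

    h′(t) = A·h(t) + B·x(t),        y(t) = C·h(t) + D·x(t),

discretized by zero-order hold (Ā = e^{ΔA}, B̄ = ΔB) and evaluated as the
recurrence h_k = Ā_k h_{k−1} + B̄_k x_k with input-dependent Δ, B, C (the
Mamba selection mechanism).  On 2-D feature maps the scan runs along four
traversal orders and the results are summed (SS2D).  The network is
trained with L = 0.4·L_wce + 0.6·L_wdice and evaluated with Dice and the
95th-percentile symmetric Hausdorff boundary distance.

The package is aimed at researchers who want a fully inspectable,
pure-NumPy reference implementation of this architecture family — every
operation, including the selective scan and its gradients, is readable
code checked against brute-force oracles — rather than peak throughput.

## Worked example

Generate 200 synthetic phantoms (64×64, 8:2 train/test split), train the
desk-scale profile for 30 epochs, and evaluate:

```bash
mambaseg generate --out data --n 200 --image-size 64 --seed 0
# wrote 160 train / 40 test pairs to data
mambaseg train --data data --out run --profile tiny --epochs 30 --seed 0
# epoch 1/30  loss 0.3380  val dice 0.1084
# epoch 2/30  loss 0.2636  val dice 0.1618
# ...
# epoch 30/30  loss 0.0652  val dice 0.7697
mambaseg eval --data data --checkpoint run/checkpoint.npz --out run
# mean dice 0.7697  hd95 8.07  precision 0.7826  recall 0.8051
```

The loss is the 0.4/0.6 cross-entropy/Dice compound; `val dice` is the
mean Dice over the held-out phantoms (1.0 = perfect overlap), and `hd95`
is in pixels (lower is better; 0 = boundaries coincide).  A Dice around
0.77 is the plateau for this five-minute CPU run: the phantoms carry
fully-developed speckle (σ/μ ≈ 0.5) and lesion contrasts down to 35%, so
the faintest lesions sit near the detectability limit (see
`docs/methods.md`).  Per-image metrics land in `run/metrics.csv`, the
per-step learning rate and loss in `run/runlog.csv`.

Complexity of the publication-scale configuration (C = 96, stage depths
[2,2,9,2], 224×224 input):

```bash
mambaseg complexity --profile full --breakdown
# parameters: 29.67 M
# forward FLOPs @ 224×224: 18.50 G (2×MAC convention)
```

See `docs/methods.md` for the model details, all conventions (HD95
boundary extraction, degenerate-mask rules, FLOP counting) and the
discussion of the complexity accounting.

## Library use

```python
from mambaseg import (PROFILES, build_model, PhantomSpec, make_dataset,
                      TrainConfig, fit, evaluate_model)

train, test = make_dataset(200, PhantomSpec(seed=0))
model = build_model(PROFILES["tiny"], seed=0)
log = fit(model, train, TrainConfig(epochs=30, seed=0))
rows, agg = evaluate_model(model, test)
print(agg)   # {'dice': ..., 'hd95': ..., 'precision': ..., 'recall': ...}
```

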