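"""Train the cascaded segmentation network at toy scale.

Builds a handful of small synthetic density cubes with voxel labels and runs
a few optimizer steps of the full three-stage cascade (SSE -> backbone ->
Calpha). At this scale the network only demonstrates that the joint loss
falls; real use would train 15 epochs on thousands of cubes.
"""

import cryotrace as ct
from cryotrace.preprocess import make_toy_cubes

samples = make_toy_cubes(4, edge=12, seed=0)
model = ct.build_ccnn(seed=0)
print("cascade filters:", {n: model.layer_filters(n)
                           for n in ("sse", "backbone", "calpha")})

model, history = ct.train_ccnn(model, samples, epochs=3, seed=0, max_steps=8)
print("loss history:", [round(h, 3) for h in history])
print(f"joint loss fell from {history[0]:.3f} to {history[-1]:.3f}; the "
      "loss is the sum of the SSE, backbone and Calpha cross-entropies with "
      "inverse-frequency class weights")

probs = model.forward(samples[0]["density"])
print("output volumes:", {k: v.shape for k, v in probs.items()},
      "— one probability per voxel per class, same grid as the input cube")
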