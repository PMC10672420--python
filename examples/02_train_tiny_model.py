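"""Train a reduced model on a single synthetic phantom (CPU, ~3 minutes).

Uses the single-image memorization preset: encoder with 4 residual blocks
and depth 16, region size M=4, 4000 optimization steps of Adam on the L1
point loss. Prints the loss trace and writes a checkpoint.
"""

from owsr import PhantomSpec, gen_vessel_phantom, tiny_overfit_config, train

image = gen_vessel_phantom(PhantomSpec(seed=3))
config = tiny_overfit_config(seed=0)

model, log = train(config, [image], out_dir="scratch_run")

for step, epoch, lr, loss in [log[0], log[9], log[99], log[999], log[-1]]:
    print(f"step {step:5d}  lr {lr:.1e}  L1 loss {loss:.4f}")
print("checkpoint written to scratch_run/model.npz")

# The loss falls from its random-init value (~2) to under 0.1: the model is
# memorizing the continuous mapping from this image's latent features to its
# pixel values at every scale between 1 and 2.
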