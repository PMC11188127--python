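# stackdenoise

Denoising of fluorescence-microscopy image stacks with a **frame-attention
transformer U-net**, trained with a two-stage scheme: pretrain one
**backbone** on pooled paired low/high-SNR data, then **fine-tune** it on a
handful (5–10) of pairs from each new experiment. A built-in simulator
generates photon-realistic synthetic stack pairs so the whole pipeline is
trainable and testable on a single CPU in minutes.

Everything — the network, reverse-mode autodiff, Adam training, tiled
inference — is implemented in NumPy; there is no deep-learning framework
dependency.

## The model

Input tensors are `[B, C, F, H, W]` (batch, channel, frame = Z or T,
height, width). The building block is a transformer-style cell:

- **convolutional K/Q/V**: 2D convolutions applied per frame produce key,
  query and value maps — no fully-connected projections;
- **frame attention**: soft attention is computed *between frames*. In the
  default `pooled` mode the scores aggregate over channels and pixels per
  head, giving an F×F attention matrix (cost linear in pixel count); a
  `pixelwise` mode (F×F scores at every pixel) is also available;
- **pre-norm residual sublayers** with instance normalization and a
  two-convolution GELU mixer.

Cells are assembled into a U-net (2 downsampling and 2 upsampling stages,
channel doubling/halving, skip concatenation) wrapped in pre-/post-convs
and a long additive skip. The post-conv is zero-initialized, so an
untrained network is exactly the identity — training starts from "do no
harm".

## CLI

```bash
# synthetic paired dataset (TIFF stacks + manifest)
stackdenoise simulate --preset smoke --seed 0 --out data/

# stage 1: backbone on pooled pairs
stackdenoise train-backbone --manifest data/manifest.yaml --preset smoke \
    --seed 0 --out backbone.ckpt

# stage 2: adapt to a new experiment with a few pairs
stackdenoise finetune --backbone backbone.ckpt --manifest new/manifest.yaml \
    --preset smoke --seed 0 --out tuned.ckpt

# denoise a stack (tiled, feather-blended)
stackdenoise infer --checkpoint tuned.ckpt --in noisy.tif --out clean.tif \
    --tile 8,256,256 --overlap 32

# PSNR / SSIM3D report on a manifest split
stackdenoise evaluate --checkpoint tuned.ckpt --manifest new/manifest.yaml \
    --split test --out report.json

# running-average robustness sweep (Avg 1..64)
stackdenoise robustness --checkpoint tuned.ckpt --out curve.json

# checkpoint inspection without loading weights
stackdenoise info --checkpoint tuned.ckpt
```

Presets: `smoke` (tiny model, minutes on CPU) and `paper-analog`
(published-scale defaults). Precedence: flags > `--config` file > preset >
built-in defaults. Exit codes: 0 success, 2 usage, 3 config/validation,
4 I/O, 5 numeric failure. Every command writes a JSON run record beside
its outputs.

## Layout

```
src/stackdenoise/
  io.py         TIFF stack + manifest I/O, percentile normalization, logging
  model.py      frame-attention cell and U-net (config, init, forward)
  _autodiff.py  minimal reverse-mode autodiff on NumPy arrays
  synth.py      phantom generator, Poisson-Gaussian noise, average series
  train.py      patch sampling, loss, Adam loops, tiled inference, checkpoints
  metrics.py    PSNR, volumetric SSIM, evaluation harnesses
  recipes.py    desk-scale reference experiments (used by acceptance)
  cli.py        `stackdenoise` command-line application
```
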