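{
  "description": "Pilot-run calibration for the GAN memorization smoke tests. Single phantom field (day6 preset, difficulty 0.3, render seed 5) resized to 32 px; ImageGAN(image_size=32, width=64, epochs=2000, batch_size=16, augment=False) trained on the target replicated 16x; best-of-64-sample mean absolute error on the [-1,1] scale. Clip pilot: single beating clip (amplitude 3, seed 4), VideoGAN(image_size=32, width=64, epochs=1000, batch_size=16, augment=True). Thresholds are the observed pilot maxima plus margin; the constant-image baseline for the field target is 0.314 and for the clip target 0.289.",
  "image_memorization_pilot_mae": [0.141, 0.188, 0.139],
  "image_memorization_threshold": 0.25,
  "clip_memorization_pilot_mae": [0.215, 0.324, 0.250],
  "clip_memorization_threshold": 0.35
}
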