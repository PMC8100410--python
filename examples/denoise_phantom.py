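"""Denoise a synthetic brain phantom and measure the PSNR gain.

Builds a 32x32x16 phantom (smooth blobs on a 0-255 scale), adds
Gaussian noise of SD 15, runs the variational denoiser, and prints the
peak signal-to-noise ratio before and after.  A higher PSNR means the
volume is closer to the clean reference; gains of several dB indicate
substantial noise removal.
"""

from adseverity.denoise import DenoiseConfig, gradient_descent_denoise, psnr
from adseverity.synthetic import make_phantom

phantom = make_phantom(shape=(32, 32, 16), n_blobs=5, noise_sigma=15.0, seed=0)
denoised = gradient_descent_denoise(phantom.noisy, DenoiseConfig(seed=0))

before = psnr(phantom.clean, phantom.noisy)
after = psnr(phantom.clean, denoised)
print(f"PSNR of noisy input : {before:.2f} dB")
print(f"PSNR after denoising: {after:.2f} dB")
print(f"improvement         : {after - before:+.2f} dB "
      "(positive = closer to the clean volume)")
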