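"""Choose the camera channel with the best root/paper contrast.

Fixture reflectance spectra mimic a measured batch: strongly blue/grey
germination papers reflect about half as much as the root between 560 and
720 nm, so the red channel separates best; white paper is bright everywhere
and no channel helps.
"""

from rootmetrics.spectra import make_fixture_spectra, normalize_to_reference, recommend_channel

fx = make_fixture_spectra(seed=0)
root = normalize_to_reference(fx.root, fx.spectralon)
papers = {
    name: normalize_to_reference(curve, fx.spectralon)
    for name, curve in fx.papers.items()
}

blue_grey = {k: papers[k] for k in ("steel_blue", "whatman_blue", "sebio_grey")}
rec = recommend_channel(root, blue_grey)
print("root/paper contrast (band means, >1 means the root is brighter):")
print(rec.contrasts.round(2).to_string())
print(f"recommended channel for blue/grey papers: {rec.channel}")

white = recommend_channel(root, {"white": papers["white"]})
print("\nwhite paper contrasts:", white.contrasts.round(2).loc["white"].to_dict())
# ~0.5 in every visible band: the white paper outshines the root everywhere,
# so no camera channel gives a usable contrast.
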