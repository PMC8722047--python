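"""Integrate per-screen CRISPR hit tables into a recurrent regulator catalog.

Hits enriched (positive adj. p < 0.05, lfc > 0) mark sensitizer candidates,
depleted hits mark resistors; only genes recurrent in >= 2 screens survive.
"""

from immunoscreen.io import load_default_screen_metadata, summarize_metadata
from immunoscreen.screens import build_catalog, classify_hits
from immunoscreen.simulate import SyntheticSpec, make_screens

# composition of the packaged 17-screen design table
screens = load_default_screen_metadata()
print("screens by cancer model:")
print(summarize_metadata(screens, "cancer_type").to_string(index=False))

# classify synthetic screens and keep recurrent hits
spec = SyntheticSpec(seed=1)
tables, _ = make_screens(spec)
classified = {sid: classify_hits(tab, alpha=0.05) for sid, tab in tables.items()}
catalog = build_catalog(classified, min_screens=2)
print(f"\ncatalog: {len(catalog)} recurrent regulators "
      f"({len(catalog.sensitizers)} sensitizers, {len(catalog.resistors)} resistors)")
print("first sensitizers:", catalog.sensitizers[:4])
# Each catalog entry lists the screens supporting it; single-screen hits are
# excluded as likely noise.
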