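"""Survey regions for an IUPAC consensus and export motifs for MEME.

Scans the synthetic regions for a CCCTC-binding-factor-like core consensus
(user-supplied; no motif database is bundled) and writes the two planted
patterns as a MEME minimal motif file.
"""

from methylmotif import (
    consensus_scan,
    default_fixture_spec,
    export_meme_minimal,
    generate_fixtures,
    parse_pattern,
)

regions, _ = generate_fixtures(default_fixture_spec(seed=7))

consensus = "CCNCC"  # stand-in core; supply a real CTCF consensus in practice
total = 0
for region in regions:
    matches = consensus_scan(region, consensus, strands="both")
    total += len(matches)
    if matches:
        first = matches[0]
        print(f"  {region.region_id} ({region.meth_class}): {len(matches)} matches, "
              f"first at {first.strand}{first.start} ({first.matched_sequence})")
print(f"{total} matches of {consensus} across {len(regions)} regions, both strands")

meme_text = export_meme_minimal(
    [(parse_pattern("CCGG*"), 31), (parse_pattern("AATT*"), 15)]
)
print("\nMEME minimal export (first lines):")
print("\n".join(meme_text.splitlines()[:14]))
# Fixed pattern positions become one-hot matrix rows; wildcard positions
# carry the background distribution, so MEME treats them as uninformative.
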