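# Approximate IUPAC consensi for common plant promoter cis-acting elements.
# These are simplified stand-ins for database definitions; supply your own
# table for production scans.
name	consensus	note
G-box	CACGTG	light responsive (approximate)
Box 4	ATTAAT	light responsive (approximate)
TCA-element	CCATCTTTTT	salicylic-acid responsive (approximate)
MBS	CAACTG	MYB binding site, drought (approximate)
ARE	AAACCA	anaerobic induction (approximate)
HSE	AAAAAATTTC	heat stress (approximate)
GARE-motif	TCTGTTG	gibberellin responsive (approximate)
circadian	CAANNNNATC	circadian control (approximate)
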