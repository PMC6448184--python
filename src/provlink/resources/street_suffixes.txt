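# USPS Publication 28 street-suffix abbreviations (subset).
# Format: VARIANT<TAB>CANONICAL  (uppercase; canonical forms map to themselves)
ALLEY	ALY
ALY	ALY
AVENUE	AVE
AVENU	AVE
AV	AVE
AVE	AVE
BOULEVARD	BLVD
BOULV	BLVD
BLVD	BLVD
CENTER	CTR
CENTRE	CTR
CTR	CTR
CIRCLE	CIR
CIR	CIR
COURT	CT
CT	CT
CRESCENT	CRES
CRES	CRES
CROSSING	XING
XING	XING
DRIVE	DR
DRV	DR
DR	DR
EXTENSION	EXT
EXT	EXT
FREEWAY	FWY
FWY	FWY
GREEN	GRN
GRN	GRN
HEIGHTS	HTS
HTS	HTS
HIGHWAY	HWY
HIWAY	HWY
HWY	HWY
LANE	LN
LN	LN
LOOP	LOOP
PARKWAY	PKWY
PKWY	PKWY
PIKE	PIKE
PLACE	PL
PL	PL
PLAZA	PLZ
PLZ	PLZ
POINT	PT
PT	PT
RIDGE	RDG
RDG	RDG
ROAD	RD
RD	RD
ROUTE	RTE
RTE	RTE
ROW	ROW
SQUARE	SQ
SQ	SQ
STREET	ST
STR	ST
ST	ST
TERRACE	TER
TERR	TER
TER	TER
TRAIL	TRL
TRL	TRL
TURNPIKE	TPKE
TPKE	TPKE
WAY	WAY
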