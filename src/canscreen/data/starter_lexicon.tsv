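term	variants	subtype	specificity	source	mean_rating	prop_at_least_2
child abuse		ABUSE	standard	investigator
abuse		ABUSE	standard	investigator
physical abuse		ABUSE	standard	investigator
emotional abuse		ABUSE	standard	investigator
violence		ABUSE	standard	investigator
neglect		ABUSE	standard	investigator
adverse childhood event	adverse childhood events|ACE	ABUSE	standard	investigator
childhood trauma		ABUSE	standard	investigator
alleged		ABUSE	standard	investigator
maltreatment		ABUSE	standard	investigator
incarcerated	incarceration	ABUSE	low	investigator
sexual abuse	SA	SEXUAL_ABUSE	standard	investigator
sexual assault		SEXUAL_ABUSE	standard	investigator
date rape		SEXUAL_ABUSE	standard	investigator
rape	raped	SEXUAL_ABUSE	standard	investigator
molestation	molested	SEXUAL_ABUSE	standard	investigator
pornography		SEXUAL_ABUSE	standard	investigator
inappropriate sexual behavior		SEXUAL_ABUSE	standard	investigator
injury to genital region		SEXUAL_ABUSE	standard	investigator
sexually transmitted disease	STD	SEXUAL_ABUSE	standard	investigator
bruise	bruises|bruising	PHYSICAL_INDICATION	standard	investigator
burn	burns	PHYSICAL_INDICATION	standard	investigator
fracture	fractures	PHYSICAL_INDICATION	standard	investigator
bleed	bleeding	PHYSICAL_INDICATION	standard	investigator
genital bleeding		PHYSICAL_INDICATION	standard	investigator
vaginal bleeding		PHYSICAL_INDICATION	standard	investigator
malnutrition		PHYSICAL_INDICATION	standard	investigator
poor living conditions		PHYSICAL_INDICATION	standard	investigator
threaten	threatened|threatening	EMOTIONAL_INDICATION	standard	investigator
humiliate	humiliated	EMOTIONAL_INDICATION	standard	investigator
posttraumatic stress disorder	PTSD	EMOTIONAL_INDICATION	standard	investigator
coercion		EMOTIONAL_INDICATION	standard	investigator
child protective services	CPS	SERVICE	standard	investigator
foster care		SERVICE	standard	investigator
foster parents	foster parent	SERVICE	standard	investigator
foster care support clinic	FCSC	SERVICE	standard	investigator
child advocacy center		SERVICE	standard	investigator
child abuse pediatrics		SERVICE	standard	investigator
police		SERVICE	low	investigator
law enforcement		SERVICE	low	investigator
case worker	caseworker	SERVICE	low	investigator
case manager		SERVICE	low	investigator
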