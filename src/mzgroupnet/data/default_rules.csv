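name,delta,note
mono-oxygenation,+1O,hydroxylation or epoxidation (net oxygen insertion)
hydrogenation,+2H,reduction of a double bond
hydration,+2H+1O,water addition across a double bond
methoxylation,+1C+2H+1O,net O-CH3 for H
methylation,+1C+2H,net CH2 insertion (SAM-dependent methyl transfer)
oxidoreduction,-2H,desaturation / dehydrogenation
oxidation,-2H+1O,net alcohol-to-carboxylic-acid type change
malonylation,+3C+2H+3O,malonyl ester formation
hexosylation,+6C+10H+5O,glycosylation with a hexose (glucose or galactose)
dihydroxylation,+2H+2O,dihydroxylation of a double bond
coumaroylation,+9C+6H+2O,p-coumaroyl ester formation
pentosylation,+5C+8H+4O,glycosylation with a pentose (xylose or arabinose)
demethylation,-1C-2H,loss of a methyl group
dehydration,-2H-1O,water loss (condensation)
deoxygenation,-1O,loss of one oxygen atom
acetylation,+2C+2H+1O,acetyl ester or amide formation
formylation,+1C+1O,formyl transfer
decarboxylation,-1C-2O,loss of CO2
carboxylation,+1C+2O,CO2 fixation
phosphorylation,+1H+3O+1P,HPO3 transfer
dephosphorylation,-1H-3O-1P,phosphate ester hydrolysis
sulfation,+3O+1S,SO3 transfer
desulfation,-3O-1S,sulfate ester hydrolysis
amination,+3H+1N-1O,reductive amination of a carbonyl
deamination,-3H-1N+1O,oxidative deamination to a carbonyl
glucuronidation,+6C+8H+6O,glucuronic acid conjugation
rhamnosylation,+6C+10H+4O,glycosylation with a deoxyhexose (rhamnose)
malylation,+4C+4H+4O,malyl ester formation
galloylation,+7C+4H+4O,galloyl ester formation
sinapoylation,+11C+10H+4O,sinapoyl ester formation
feruloylation,+10C+8H+3O,feruloyl ester formation
caffeoylation,+9C+6H+3O,caffeoyl ester formation
benzoylation,+7C+4H+1O,benzoyl ester formation
cinnamoylation,+9C+6H+1O,cinnamoyl ester formation
prenylation,+5C+8H,C5 isoprenoid transfer
geranylation,+10C+16H,C10 isoprenoid transfer
ethylation,+2C+4H,net C2H4 insertion (or double methylation)
propionylation,+3C+4H+1O,propionyl ester or amide formation
butyrylation,+4C+6H+1O,butyryl ester or amide formation
crotonylation,+4C+4H+1O,crotonyl transfer
succinylation,+4C+4H+3O,succinyl ester formation
glycine-conjugation,+2C+3H+1N+1O,glycine amide conjugation
taurine-conjugation,+2C+5H+1N+2O+1S,taurine amide conjugation
glutathionylation,+10C+15H+3N+6O+1S,glutathione conjugation
cysteinylation,+3C+5H+1N+1O+1S,cysteine conjugation
nitration,-1H+1N+2O,NO2 for H
thiolation,+1S,net sulfur insertion
farnesylation,+15C+24H,C15 isoprenoid transfer
lauroylation,+12C+22H+1O,C12 acyl transfer
myristoylation,+14C+26H+1O,C14 acyl transfer
palmitoylation,+16C+30H+1O,C16 acyl transfer
stearoylation,+18C+34H+1O,C18 acyl transfer
adenylation,+10C+12H+5N+6O+1P,AMP transfer
uridylylation,+9C+11H+2N+8O+1P,UMP transfer
biotinylation,+10C+14H+2N+2O+1S,biotin amide conjugation
diphosphorylation,+2H+6O+2P,transfer of two phosphoryl groups
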