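id,name,unit,group,group_name,main_weight,polarity,weight,rank
S11,Area of agricultural land,thousand hectares,S1,Sustainable development of resources and environment,0.3341,negative,0.1176,4
S12,Area of cultivated land,thousand hectares,S1,Sustainable development of resources and environment,0.3341,negative,0.0994,5
S13,Area of orchard,thousand hectares,S1,Sustainable development of resources and environment,0.3341,positive,0.0343,9
S14,Area of forest,thousand hectares,S1,Sustainable development of resources and environment,0.3341,positive,0.0408,8
S15,Area of pastureland,thousand hectares,S1,Sustainable development of resources and environment,0.3341,positive,0.0205,15
S16,Area of land for other agricultural use,thousand hectares,S1,Sustainable development of resources and environment,0.3341,negative,0.0207,14
S21,Construction land,thousand hectares,S2,Economic sustainable development,0.3780,negative,0.1185,3
S22,Residential site and independent mining land,thousand hectares,S2,Economic sustainable development,0.3780,negative,0.1233,2
S23,Land for transportation,thousand hectares,S2,Economic sustainable development,0.3780,positive,0.0304,10
S24,Land for irrigation facility,thousand hectares,S2,Economic sustainable development,0.3780,positive,0.0410,7
S25,Total investment in environmental pollution abatement,hundred million yuan,S2,Economic sustainable development,0.3780,positive,0.0111,16
S26,Waste water discharge,hundred million ton,S2,Economic sustainable development,0.3780,negative,0.0090,17
S31,National territorial land area,ten thousand hectares,S3,Social sustainable development,0.2879,positive,0.1836,1
S32,Per capita GDP,yuan,S3,Social sustainable development,0.2879,positive,0.0739,6
S33,Urbanization rate,%,S3,Social sustainable development,0.2879,positive,0.0301,11
S34,Food supply per capita,kg/person,S3,Social sustainable development,0.2879,positive,0.0230,12
S35,Natural population growth rate,%,S3,Social sustainable development,0.2879,negative,0.0227,13
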