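population_id,location,country,range_class,latitude,longitude,altitude_m,collection_year,n_samples,haplotypes,group
UK01,"Killearn, Stirling","Scotland, UK",introduced,56.00297,-4.35907,,2016,2,J,2
UK02,"Forth, South Lanarkshire","Scotland, UK",introduced,56.13263,-3.93942,,2016,2,J,2
UK03,"River Till, Northumberland","England, UK",introduced,55.67944,-2.18283,,2016,1,E,1B
UK04,"Norham, Northumberland","England, UK",introduced,55.73161,-2.14806,,2016,2,M,1B
UK05,"River Tweed, Northumberland","England, UK",introduced,55.67851,-2.21306,,2016,1,E,1B
UK06,"Harrogate, North Yorkshire","England, UK",introduced,54.36659,-1.92535,,1914,1,C,1A
UK07,"Newbus Grange, Durham","England, UK",introduced,54.48018,-1.50706,,2016,2,J,2
UK08,"Colden Clough, West Yorkshire","England, UK",introduced,53.74747,-2.03029,,2016,2,G,1B
UK09,"Gorpley Clough, West Yorkshire","England, UK",introduced,53.70696,-2.12721,,2016,2,J,2
UK10,"Stanley Marsh, West Yorkshire","England, UK",introduced,53.70769,-1.47883,,2016,2,J,2
UK11,"Meanwood Grove, West Yorkshire","England, UK",introduced,53.61275,-1.51271,,1908,1,N,1B
UK12,"Boston, Lincolnshire","England, UK",introduced,53.36102,-0.23627,,1945,1,E,1B
UK13,"Framingham Pigot, Norfolk","England, UK",introduced,52.585,1.36972,,2016,2,J,2
UK14,"Harmondsworth Moor, Middlesex","England, UK",introduced,51.493,-0.48321,,2016,8,A,1A
UK15,"Silwood Park, Berkshire","England, UK",introduced,51.40756,-0.64374,,2016,4,E,1B
UK16,"Sunningdale, Berkshire","England, UK",introduced,51.39426,-0.63567,,2016,2,E,1B
UK17,"Bexley, Kent","England, UK",introduced,51.44735,0.16217,,2016,2,E,1B
UK18,"Gatwick, West Sussex","England, UK",introduced,51.15257,-0.19838,,2016,2,E,1B
UK19,"Andover, Hampshire","England, UK",introduced,51.20461,-1.17105,,1898,1,E,1B
UK20,"Loughwood, Devon","England, UK",introduced,50.92382,-4.01043,,1916,1,E,1B
UK21,"Bovey Tracey, Devon","England, UK",introduced,50.60359,-3.64852,,1918,1,K,1B
UK22,"Looe, Cornwall","England, UK",introduced,50.50383,-4.60633,,1901,1,E,1B
UK23,"Nanstallon, Cornwall","England, UK",introduced,50.47344,-4.7692,,2016,1,E,1B
UK24,"Lanivet, Cornwall","England, UK",introduced,50.45195,-4.76513,,2016,4,E,1B
UK25,"Helligan and Grogley Woods, Cornwall","England, UK",introduced,50.47995,-4.79778,,2016,2,E,1B
UK26,"Polmorla, Cornwall","England, UK",introduced,50.501,-4.85685,,2016,2,E,1B
UK27,"Lampeter, Ceredigion","Wales, UK",introduced,52.11126,-4.07258,,2016,2,E,1B
UK28,"Rhosmaen, Carmarthenshire","Wales, UK",introduced,51.92316,-3.97646,,2016,2,E,1B
UK29,"Swansea Vale, Swansea","Wales, UK",introduced,51.66526,-3.9036,,2016,2,E,1B
UK30,"Clyne Valley, Swansea","Wales, UK",introduced,51.59975,-3.99761,,2016,2,E;J,"1B,2"
UK31,Unknown,UK,introduced,,,,,1,O,1A
IR01,"Carragh, Kildare",Ireland,introduced,53.23044,-6.72179,,2016,2,E,1B
IR02,"Bunclody, Wexford",Ireland,introduced,52.65607,-6.65031,,2016,2,A,1A
IR03,"Kilkenny, Kilkenny",Ireland,introduced,52.65206,-7.24265,,2016,2,E;H,1B
IN01,"Tangmarg, Jammu and Kashmir",India,native,34.0,74.4,1829,1956,1,D,1B
IN02,"Wangat Valley, Jammu and Kashmir",India,native,34.3,74.9,,1940,1,E,1B
IN03,"Liddar Valley, Jammu and Kashmir",India,native,33.7,75.1,3048,1893,1,U,1A
IN04,"Palgam, Jammu and Kashmir",India,native,34.0,75.3,,1913,1,V,1B
IN05,"Sumadah Chun, Ladakh, Jammu and Kashmir",India,native,33.8,77.0,4115,1947,1,L,1A
IN06,"Solang, Solang Valley, Himachal Pradesh",India,native,32.32293,77.15746,2450,2009,1,R,1B
IN07,"Rohtang, Kullu Valley, Himachal Pradesh",India,native,32.32983,77.21162,3067,2009,2,W,1B
IN08,"Jibhi, Himachal Pradesh",India,native,31.57635,77.36196,1938,2009,1,S,1B
IN09,"Dimanjan Dogri, Baspa Valley, Himachal Pradesh",India,native,31.3,78.2,3810,1939,1,I,1B
IN10,"Gauges Valley, Tihri-Gathwal, Himachal Pradesh",India,native,30.7,78.9,1829,1881,1,F,1B
IN11,"Jammu and Kashmir",India,native,,,,1945,1,A,1A
PA01,"Jalkhand, Khyber Pakhtunkhwa",Pakistan,native,34.97462,73.92942,3098,2009,1,B,1A
PA02,"Batakundi, Khyber Pakhtunkhwa",Pakistan,native,34.9337,73.75732,2651,2009,1,A,1A
PA03,"Lalazar, Khyber Pakhtunkhwa",Pakistan,native,34.91687,73.76405,3130,2009,1,B,1A
PA04,"Naran Lake, Khyber Pakhtunkhwa",Pakistan,native,34.90726,73.67806,2829,2009,1,T,1B
PA05,"Naran, Khyber Pakhtunkhwa",Pakistan,native,34.86858,73.6088,2300,2009,1,P,1A
PA06,Kaghan Valley,Pakistan,native,34.5,73.3,,1954,1,Q,1B
PA07,"Thandiani, Hazara",Pakistan,native,34.2,73.3,2591,1956,1,P,1A
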